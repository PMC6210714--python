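"""Convenience composition: raw cohort -> model-ready paired signals."""

from __future__ import annotations

import numpy as np

from .dataset import PairedSignal, make_paired
from .nmf import ActivationDecomposition, extract_model_input
from .preprocess import PreprocessConfig, preprocess_recording
from .synthetic import SyntheticRecording


def recording_to_paired(rec: SyntheticRecording, Q: int,
                        pre: PreprocessConfig = PreprocessConfig(),
                        s: int = 2, fraction: float = 0.25, seed: int = 0,
                        nmf_time_stride: int = 20,
                        ) -> tuple[PairedSignal, ActivationDecomposition]:
    """Preprocess one recording, select channels by NMF, cut into Q-point cycles."""
    env = preprocess_recording(rec, pre)
    averaged, decomp = extract_model_input(env, s=s, fraction=fraction, seed=seed,
                                           time_stride=nmf_time_stride)
    level = float(rec.force_levels[0]) if rec.force_levels else float("nan")
    paired = make_paired(averaged, env.force_norm, env.cycle_bounds, Q,
                         subject_id=rec.subject_id, level=level)
    return paired, decomp


def cohort_to_paired(recordings: list[SyntheticRecording], Q: int,
                     pre: PreprocessConfig = PreprocessConfig(),
                     s: int = 2, fraction: float = 0.25, seed: int = 0,
                     nmf_time_stride: int = 20) -> list[PairedSignal]:
    """Run the conditioning + selection pipeline over a whole cohort."""
    ss = np.random.SeedSequence(seed)
    out = []
    for rec, child in zip(recordings, ss.spawn(len(recordings))):
        paired, _ = recording_to_paired(
            rec, Q, pre=pre, s=s, fraction=fraction,
            seed=int(child.generate_state(1)[0] % (2 ** 31)),
            nmf_time_stride=nmf_time_stride)
        out.append(paired)
    return out
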