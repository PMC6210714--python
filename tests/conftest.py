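import numpy as np
import pytest

import emgforce as ef

#: short trapezoid (0.4 s ramp / 0.8 s hold / 0.2 s rest at 1 kHz) for cheap
#: structural tests; spectral tests use the full-length default pattern.
SHORT_PATTERN = ef.ForcePattern(0.5, ramp_s=0.4, hold_s=0.8, rest_s=0.2, fs_hz=1000)


@pytest.fixture(scope="session")
def small_recording() -> ef.SyntheticRecording:
    """Four short cycles, default subject, a few bad channels."""
    subject = ef.SubjectModel(seed=7, bad_channels=frozenset({0, 37, 90}))
    force, bounds = ef.generate_force_trace(SHORT_PATTERN, 4, seed=7)
    return ef.generate_hd_semg(force, ef.GridSpec(), subject,
                               cycle_bounds=bounds, force_levels=[0.5] * 4)


@pytest.fixture(scope="session")
def mid_recording() -> ef.SyntheticRecording:
    """Six full-length (7 s) cycles at 50% MVC; realistic time scales."""
    subject = ef.SubjectModel(seed=3)
    force, bounds = ef.generate_force_trace(ef.ForcePattern(0.5), 6, seed=3)
    return ef.generate_hd_semg(force, ef.GridSpec(), subject,
                               cycle_bounds=bounds, force_levels=[0.5] * 6)


@pytest.fixture(scope="session")
def mid_envelopes(mid_recording) -> ef.EnvelopeSet:
    return ef.preprocess_recording(mid_recording)


def make_trapezoid_pool(n_cycles: int, Q: int, level: float = 0.5,
                        subject_id: int = 0, noise: float = 0.0,
                        seed: int = 0) -> ef.PairedSignal:
    """Hand-built paired signal: x and y are the same trapezoid per cycle."""
    rng = np.random.default_rng(seed)
    n_ramp, n_rest = Q // 4, Q // 8
    cyc = np.concatenate([
        np.linspace(0, level, n_ramp, endpoint=False),
        np.full(Q - n_ramp - n_rest, level),
        np.linspace(level, 0, n_rest, endpoint=False),
    ])
    y = np.tile(cyc, n_cycles)
    x = y + noise * rng.standard_normal(y.size) if noise else y.copy()
    return ef.PairedSignal(x=x, y=y, Q=Q, subject_id=subject_id, level=level)
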