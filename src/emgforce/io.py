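"""Array-container persistence for recordings and sample sets.

Recordings live in an HDF5 file, one group per recording, with ``emg`` and
``force`` datasets plus the sampling rate, grid dimensions, subject id,
cycle bounds, bad channels and ground-truth activation weights as
attributes/datasets.  A delimited-text export (one column per channel,
force last) is provided for interoperability.
"""

from __future__ import annotations

import numpy as np

try:
    import h5py
except ImportError:  # pragma: no cover
    h5py = None

from .dataset import SampleSet
from .synthetic import GridSpec, SyntheticRecording


def _require_h5py():
    if h5py is None:  # pragma: no cover
        raise ImportError("h5py is required for HDF5 persistence")


def save_recordings(path, recordings: list[SyntheticRecording]) -> None:
    _require_h5py()
    with h5py.File(path, "w") as f:
        for i, rec in enumerate(recordings):
            g = f.create_group(f"recording_{i:04d}")
            g.create_dataset("emg", data=rec.emg)
            g.create_dataset("force", data=rec.force)
            g.create_dataset("cycle_bounds", data=np.asarray(rec.cycle_bounds, dtype=int).reshape(-1, 2))
            g.create_dataset("truth_weights", data=rec.truth_weights)
            g.attrs["fs_hz"] = rec.fs_hz
            g.attrs["subject_id"] = rec.subject_id
            g.attrs["n_rows"] = rec.grid.n_rows
            g.attrs["n_cols"] = rec.grid.n_cols
            g.attrs["pitch_mm"] = rec.grid.pitch_mm
            g.attrs["bad_channels"] = sorted(rec.bad_channels)
            g.attrs["force_levels"] = list(rec.force_levels)


def load_recordings(path) -> list[SyntheticRecording]:
    _require_h5py()
    out = []
    with h5py.File(path, "r") as f:
        for name in sorted(f):
            g = f[name]
            grid = GridSpec(int(g.attrs["n_rows"]), int(g.attrs["n_cols"]),
                            float(g.attrs["pitch_mm"]))
            out.append(SyntheticRecording(
                emg=g["emg"][...],
                force=g["force"][...],
                fs_hz=float(g.attrs["fs_hz"]),
                cycle_bounds=[tuple(b) for b in g["cycle_bounds"][...]],
                force_levels=[float(v) for v in g.attrs["force_levels"]],
                truth_weights=g["truth_weights"][...],
                bad_channels=frozenset(int(c) for c in g.attrs["bad_channels"]),
                subject_id=int(g.attrs["subject_id"]),
                grid=grid,
            ))
    return out


def export_recording_csv(path, rec: SyntheticRecording) -> None:
    """One column per channel, the force trace last; tab-delimited."""
    data = np.vstack([rec.emg, rec.force[None, :]]).T
    header = "\t".join([f"ch{i:03d}" for i in range(rec.n_channels)] + ["force"])
    np.savetxt(path, data, delimiter="\t", header=header, comments="")


def save_sample_set(path, sample_set: SampleSet) -> None:
    _require_h5py()
    with h5py.File(path, "w") as f:
        f.create_dataset("x", data=sample_set.x)
        f.create_dataset("y", data=sample_set.y)
        f.create_dataset("starts", data=sample_set.starts)
        prov = np.asarray(sample_set.provenance, dtype=float).reshape(-1, 2)
        f.create_dataset("provenance", data=prov)
        f.attrs["Q"] = sample_set.Q
        f.attrs["role"] = sample_set.role
        f.attrs["seed"] = sample_set.seed


def load_sample_set(path) -> SampleSet:
    _require_h5py()
    with h5py.File(path, "r") as f:
        prov = [(int(s), float(l)) for s, l in f["provenance"][...]]
        return SampleSet(x=f["x"][...], y=f["y"][...], Q=int(f.attrs["Q"]),
                         role=str(f.attrs["role"]), provenance=prov,
                         starts=f["starts"][...].astype(int),
                         seed=int(f.attrs["seed"]))
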