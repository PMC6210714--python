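"""Synthetic high-density sEMG / force cohort generation.

Emulates an isometric elbow-flexion acquisition: a 16 x 8 electrode grid
(128 channels) sampled at 1000 Hz, trapezoidal force cycles (linear ramp to
a target %MVC, plateau, relaxation), and force-modulated broadband sEMG.
Each channel carries an independent Gaussian carrier band-limited to
20-450 Hz whose instantaneous amplitude is ``weight * gain * force**alpha``,
plus white baseline noise and a small common 50 Hz line component.  The
spatial weights form a 2-D Gaussian bump over the grid ("activation map"),
and a few channels are corrupted (flat-lined or rail-saturated) the way
real grids produce abnormal outputs.

Everything is deterministic given the seeds carried by the inputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps


@dataclass(frozen=True)
class GridSpec:
    """Electrode grid geometry; channels are numbered row-major from 0."""

    n_rows: int = 16
    n_cols: int = 8
    pitch_mm: float = 8.0

    def __post_init__(self):
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")

    @property
    def n_channels(self) -> int:
        return self.n_rows * self.n_cols

    def coords(self) -> np.ndarray:
        """(n_channels, 2) array of (row, col) positions."""
        r, c = np.divmod(np.arange(self.n_channels), self.n_cols)
        return np.stack([r, c], axis=1).astype(float)

    def neighbors(self, channel: int) -> list[int]:
        """4-connected neighbors of a channel index."""
        r, c = divmod(channel, self.n_cols)
        out = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            if 0 <= rr < self.n_rows and 0 <= cc < self.n_cols:
                out.append(rr * self.n_cols + cc)
        return out


@dataclass(frozen=True)
class ForcePattern:
    """One trapezoidal contraction cycle: ramp, hold, rest."""

    target_level: float
    ramp_s: float = 2.0
    hold_s: float = 4.0
    rest_s: float = 1.0
    fs_hz: float = 1000.0

    def __post_init__(self):
        if not 0.0 < self.target_level <= 1.0:
            raise ValueError(f"target_level must be in (0, 1], got {self.target_level}")
        if min(self.ramp_s, self.hold_s, self.rest_s) <= 0:
            raise ValueError("all durations must be positive")
        if self.fs_hz <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def cycle_samples(self) -> int:
        return int(round((self.ramp_s + self.hold_s + self.rest_s) * self.fs_hz))


@dataclass(frozen=True)
class SubjectModel:
    """Per-subject generative parameters (inter-subject variability)."""

    gain: float = 3.0
    activation_center: tuple[float, float] = (7.5, 3.5)
    activation_spread: float = 2.5
    exponent_alpha: float = 1.0
    baseline_noise: float = 0.1
    line_interference_amp: float = 0.02
    bad_channels: frozenset[int] = frozenset()
    seed: int = 0

    def __post_init__(self):
        if self.gain <= 0 or self.activation_spread <= 0:
            raise ValueError("gain and activation_spread must be positive")
        if self.exponent_alpha <= 0:
            raise ValueError("exponent_alpha must be positive")
        if self.baseline_noise < 0 or self.line_interference_amp < 0:
            raise ValueError("noise amplitudes must be non-negative")


@dataclass
class SyntheticRecording:
    """Raw multi-channel sEMG with its force trace and ground truth."""

    emg: np.ndarray                      # (channels, samples), arbitrary units
    force: np.ndarray                    # (samples,), fraction of MVC
    fs_hz: float
    cycle_bounds: list[tuple[int, int]]  # half-open (start, end) sample spans
    force_levels: list[float]            # per-cycle target level
    truth_weights: np.ndarray            # (channels,) ground-truth activation
    bad_channels: frozenset[int] = frozenset()
    subject_id: int = 0
    grid: GridSpec = field(default_factory=GridSpec)

    def __post_init__(self):
        if self.emg.shape[1] != self.force.shape[0]:
            raise ValueError("emg and force must share the sample count")

    @property
    def n_channels(self) -> int:
        return self.emg.shape[0]


def activation_map(grid: GridSpec, center: tuple[float, float], spread: float) -> np.ndarray:
    """2-D Gaussian bump evaluated at grid nodes; peak value 1."""
    d2 = ((grid.coords() - np.asarray(center, dtype=float)) ** 2).sum(axis=1)
    return np.exp(-d2 / (2.0 * spread ** 2))


def generate_force_trace(pattern: ForcePattern, n_cycles: int, seed: int = 0,
                         jitter_amp: float = 0.01) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Repeat the trapezoidal cycle ``n_cycles`` times.

    ``jitter_amp`` adds smooth seeded tracking error (fraction of MVC,
    <= 2% is realistic); set 0 to disable.  Returns the force trace in
    [0, 1] and the half-open per-cycle sample spans.
    """
    if n_cycles < 0:
        raise ValueError("n_cycles must be non-negative")
    if jitter_amp > 0.02:
        raise ValueError("tracking jitter above 2% MVC is not plausible")
    fs = pattern.fs_hz
    n_ramp = int(round(pattern.ramp_s * fs))
    n_hold = int(round(pattern.hold_s * fs))
    n_cycle = pattern.cycle_samples
    n_rest = n_cycle - n_ramp - n_hold
    lvl = pattern.target_level

    cycle = np.concatenate([
        np.linspace(0.0, lvl, n_ramp, endpoint=False),
        np.full(n_hold, lvl),
        np.linspace(lvl, 0.0, n_rest, endpoint=False),
    ])
    force = np.tile(cycle, n_cycles)
    bounds = [(i * n_cycle, (i + 1) * n_cycle) for i in range(n_cycles)]
    if n_cycles and jitter_amp > 0:
        rng = np.random.default_rng(seed)
        # smooth (~1 Hz) tracking wander, zero during rests
        n = force.size
        t = np.arange(n) / fs
        phases = rng.uniform(0, 2 * np.pi, size=3)
        freqs = rng.uniform(0.3, 1.2, size=3)
        wander = sum(np.sin(2 * np.pi * f * t + p) for f, p in zip(freqs, phases)) / 3.0
        force = np.clip(force + jitter_amp * wander * (force > 0), 0.0, 1.0)
    return force, bounds


def _bandlimited_noise(rng: np.random.Generator, n_channels: int, n_samples: int,
                      fs: float, band: tuple[float, float] = (20.0, 450.0)) -> np.ndarray:
    lo, hi = band
    hi = min(hi, 0.45 * fs)
    if n_samples == 0:
        return np.empty((n_channels, 0))
    taps = sps.firwin(101, [lo, hi], fs=fs, pass_zero=False, window="hann")
    white = rng.standard_normal((n_channels, n_samples))
    padlen = min(3 * len(taps), n_samples - 1)
    carrier = sps.filtfilt(taps, [1.0], white, axis=1, padlen=padlen)
    # renormalize to unit variance so `gain` has a fixed meaning
    carrier /= carrier.std(axis=1, keepdims=True)
    return carrier


def generate_hd_semg(force: np.ndarray, grid: GridSpec, subject: SubjectModel,
                     fs_hz: float = 1000.0,
                     cycle_bounds: list[tuple[int, int]] | None = None,
                     force_levels: list[float] | None = None,
                     subject_id: int = 0) -> SyntheticRecording:
    """Synthesize the grid recording driven by a force trace in [0, 1]."""
    force = np.asarray(force, dtype=float)
    if force.size and (force.min() < 0 or force.max() > 1):
        raise ValueError("force trace must lie within [0, 1]")
    bad = frozenset(subject.bad_channels)
    if not bad <= set(range(grid.n_channels)):
        raise ValueError("bad_channels outside the grid")

    rng = np.random.default_rng(subject.seed)
    n = force.size
    weights = activation_map(grid, subject.activation_center, subject.activation_spread)
    carriers = _bandlimited_noise(rng, grid.n_channels, n, fs_hz)
    amplitude = subject.gain * force ** subject.exponent_alpha
    emg = weights[:, None] * amplitude[None, :] * carriers
    if subject.baseline_noise > 0:
        emg += subject.baseline_noise * rng.standard_normal(emg.shape)
    if subject.line_interference_amp > 0:
        t = np.arange(n) / fs_hz
        phase = rng.uniform(0, 2 * np.pi)
        emg += subject.line_interference_amp * np.sin(2 * np.pi * 50.0 * t + phase)

    rail = subject.gain * 2.0
    for ch in sorted(bad):
        if rng.random() < 0.5:
            emg[ch] = 0.0                       # flat-lined contact
        else:
            emg[ch] = rail if rng.random() < 0.5 else -rail  # saturated

    return SyntheticRecording(
        emg=emg, force=force, fs_hz=fs_hz,
        cycle_bounds=list(cycle_bounds) if cycle_bounds is not None else [(0, n)] if n else [],
        force_levels=list(force_levels) if force_levels is not None else [],
        truth_weights=weights, bad_channels=bad, subject_id=subject_id, grid=grid,
    )


def draw_subject(rng: np.random.Generator, grid: GridSpec, n_bad: tuple[int, int] = (2, 4),
                 seed: int | None = None) -> SubjectModel:
    """Draw one subject's generative parameters from seeded distributions."""
    center = (rng.uniform(0.3 * grid.n_rows, 0.7 * grid.n_rows),
              rng.uniform(0.3 * grid.n_cols, 0.7 * grid.n_cols))
    k = int(rng.integers(n_bad[0], n_bad[1] + 1))
    bad = frozenset(int(c) for c in rng.choice(grid.n_channels, size=k, replace=False))
    return SubjectModel(
        gain=float(rng.uniform(2.0, 4.0)),
        activation_center=center,
        activation_spread=float(rng.uniform(2.0, 3.0)),
        exponent_alpha=float(rng.uniform(0.9, 1.3)),
        baseline_noise=0.1,
        line_interference_amp=float(rng.uniform(0.01, 0.03)),
        bad_channels=bad,
        seed=int(seed if seed is not None else rng.integers(2 ** 31)),
    )


def make_cohort(n_subjects: int, levels: list[ForcePattern], cycles_per_level: int,
                master_seed: int = 0, grid: GridSpec | None = None,
                jitter_amp: float = 0.01) -> list[SyntheticRecording]:
    """Generate one recording per subject x force level.

    Subject parameters vary across subjects (seeded from ``master_seed``);
    output is bit-for-bit reproducible for a given master seed.
    """
    if n_subjects < 1:
        raise ValueError("need at least one subject")
    if not levels:
        raise ValueError("levels must be non-empty")
    grid = grid or GridSpec()
    ss = np.random.SeedSequence(master_seed)
    recs: list[SyntheticRecording] = []
    for subj_idx, subj_ss in enumerate(ss.spawn(n_subjects)):
        sub_seeds = subj_ss.generate_state(2 * len(levels) + 1)
        subject = draw_subject(np.random.default_rng(subj_ss), grid,
                               seed=int(sub_seeds[0] % (2 ** 31)))
        for li, pattern in enumerate(levels):
            force, bounds = generate_force_trace(
                pattern, cycles_per_level,
                seed=int(sub_seeds[1 + li] % (2 ** 31)), jitter_amp=jitter_amp)
            trial_subject = SubjectModel(
                **{**subject.__dict__,
                   "seed": int(sub_seeds[1 + len(levels) + li] % (2 ** 31))})
            rec = generate_hd_semg(
                force, grid, trial_subject, fs_hz=pattern.fs_hz,
                cycle_bounds=bounds,
                force_levels=[pattern.target_level] * cycles_per_level,
                subject_id=subj_idx)
            recs.append(rec)
    return recs
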