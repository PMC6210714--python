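"""Training/development/testing set construction.

Two ideas from the study design live here:

* **Random truncation.** A pool of P contraction cycles of Q points each is
  concatenated into a P*Q record; R start indices are drawn uniformly (with
  replacement) from the 1-based range [1, (P-1)*Q] and the Q-point windows
  starting there become samples.  Every admissible window fits inside the
  record, and windows cut across cycle boundaries, which is precisely what
  gives the trained models their varied-pattern robustness.

* **Allocation circumstances.** Cycles are split at contraction-cycle
  granularity into train/dev/test pools for the subject-dependent (one
  subject, 80/10/10), multi-subject (pooled 80/10 train/dev, per-subject
  test) and subject-independent (leave-one-subject-out, 90/10) designs.

Cycles from different recordings are only ever concatenated within one
(subject, level) pool, so truncation windows never mix subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class PairedSignal:
    """Concatenated whole cycles of the averaged sEMG input and force target."""

    x: np.ndarray           # (n_cycles * Q,)
    y: np.ndarray           # (n_cycles * Q,)
    Q: int                  # points per cycle
    subject_id: int = 0
    level: float = float("nan")

    def __post_init__(self):
        if self.x.shape != self.y.shape:
            raise ValueError("x and y must have equal length")
        if self.x.size % self.Q:
            raise ValueError("length must be a whole number of Q-point cycles")

    @property
    def n_cycles(self) -> int:
        return self.x.size // self.Q


@dataclass
class SampleSet:
    """Fixed-length (Q-point) input/target pairs with provenance."""

    x: np.ndarray           # (R, Q)
    y: np.ndarray           # (R, Q)
    Q: int
    role: str = "train"     # train | dev | test
    provenance: list[tuple[int, float]] = field(default_factory=list)
    starts: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    seed: int = 0

    def __len__(self) -> int:
        return self.x.shape[0]


def resample_cycle(seg: np.ndarray, Q: int) -> np.ndarray:
    """Linearly resample one cycle to exactly Q points."""
    n = seg.size
    if n == Q:
        return seg.copy()
    return np.interp(np.linspace(0.0, n - 1, Q), np.arange(n), seg)


def make_paired(x: np.ndarray, y: np.ndarray, cycle_bounds: list[tuple[int, int]],
                Q: int, subject_id: int = 0, level: float = float("nan"),
                method: str = "resample") -> PairedSignal:
    """Cut a trace pair into cycles of exactly Q points.

    ``method="resample"`` linearly interpolates each cycle to Q points
    (the default; tolerates cycle lengths that differ from Q).
    ``method="crop"`` keeps the first Q points and requires every cycle to
    be at least Q long.
    """
    xs, ys = [], []
    for start, end in cycle_bounds:
        xs_seg, ys_seg = x[start:end], y[start:end]
        if method == "resample":
            xs.append(resample_cycle(xs_seg, Q))
            ys.append(resample_cycle(ys_seg, Q))
        elif method == "crop":
            if end - start < Q:
                raise ValueError(f"cycle of {end - start} points shorter than Q={Q}")
            xs.append(xs_seg[:Q].copy())
            ys.append(ys_seg[:Q].copy())
        else:
            raise ValueError(f"unknown method {method!r}")
    return PairedSignal(x=np.concatenate(xs) if xs else np.empty(0),
                        y=np.concatenate(ys) if ys else np.empty(0),
                        Q=Q, subject_id=subject_id, level=level)


def split_cycles(sig: PairedSignal) -> list[PairedSignal]:
    """Explode a multi-cycle signal into single-cycle signals."""
    Q = sig.Q
    return [PairedSignal(sig.x[i * Q:(i + 1) * Q].copy(),
                         sig.y[i * Q:(i + 1) * Q].copy(),
                         Q, sig.subject_id, sig.level)
            for i in range(sig.n_cycles)]


def _regroup(cycles: list[PairedSignal]) -> list[PairedSignal]:
    """Concatenate single-cycle signals into one pool per subject.

    Cycles from different force levels are pooled (truncation windows may
    cross levels, as in multi-force training) but subjects stay separate.
    The pool keeps the level label only when it is unique.
    """
    groups: dict[int, list[PairedSignal]] = {}
    for c in cycles:
        groups.setdefault(c.subject_id, []).append(c)
    out = []
    for subj, members in groups.items():
        levels = {m.level for m in members}
        out.append(PairedSignal(
            x=np.concatenate([m.x for m in members]),
            y=np.concatenate([m.y for m in members]),
            Q=members[0].Q, subject_id=subj,
            level=levels.pop() if len(levels) == 1 else float("nan")))
    return out


@dataclass
class Allocation:
    train: list[PairedSignal]
    dev: list[PairedSignal]
    test: dict[int, list[PairedSignal]]   # per-subject test pools


CIRCUMSTANCES = ("subject_dependent", "multi_subject", "subject_independent")


def allocate(signals: list[PairedSignal], circumstance: str,
             subject: int | None = None, seed: int = 0) -> Allocation:
    """Split cycles into train/dev/test pools for one circumstance.

    ``subject`` names the single subject (subject_dependent) or the
    held-out subject (subject_independent); it is ignored for
    multi_subject.  Shuffling is at contraction-cycle granularity.
    """
    if circumstance not in CIRCUMSTANCES:
        raise ValueError(f"unknown circumstance {circumstance!r}")
    rng = np.random.default_rng(seed)
    by_subject: dict[int, list[PairedSignal]] = {}
    for s in signals:
        by_subject.setdefault(s.subject_id, []).append(s)

    def shuffled_cycles(sigs: list[PairedSignal]) -> list[PairedSignal]:
        cyc = [c for s in sigs for c in split_cycles(s)]
        rng.shuffle(cyc)
        return cyc

    if circumstance == "subject_dependent":
        if subject is None:
            if len(by_subject) != 1:
                raise ValueError("subject must be given when several are present")
            subject = next(iter(by_subject))
        if subject not in by_subject:
            raise ValueError(f"subject {subject} not in the cohort")
        cyc = shuffled_cycles(by_subject[subject])
        n = len(cyc)
        n_tr = int(n * 0.8)
        n_dev = (n - n_tr) // 2
        return Allocation(train=_regroup(cyc[:n_tr]),
                          dev=_regroup(cyc[n_tr:n_tr + n_dev]),
                          test={subject: _regroup(cyc[n_tr + n_dev:])})

    if circumstance == "multi_subject":
        train, dev, test = [], [], {}
        for subj in sorted(by_subject):
            cyc = shuffled_cycles(by_subject[subj])
            n = len(cyc)
            n_tr = int(n * 0.8)
            n_dev = (n - n_tr) // 2
            train.extend(cyc[:n_tr])
            dev.extend(cyc[n_tr:n_tr + n_dev])
            test[subj] = _regroup(cyc[n_tr + n_dev:])
        return Allocation(train=_regroup(train), dev=_regroup(dev), test=test)

    # subject_independent
    if len(by_subject) < 2:
        raise ValueError("subject_independent needs at least two subjects")
    if subject not in by_subject:
        raise ValueError(f"held-out subject {subject} not in the cohort")
    train, dev = [], []
    for subj in sorted(by_subject):
        if subj == subject:
            continue
        cyc = shuffled_cycles(by_subject[subj])
        n_tr = int(len(cyc) * 0.9)
        train.extend(cyc[:n_tr])
        dev.extend(cyc[n_tr:])
    return Allocation(train=_regroup(train), dev=_regroup(dev),
                      test={subject: _regroup(by_subject[subject])})


def random_truncation(paired: list[PairedSignal] | PairedSignal, Q: int, R: int,
                      seed: int = 0, role: str = "train") -> SampleSet:
    """Draw R uniformly-random Q-point windows from the cycle pools.

    Start indices follow the 1-based convention: within a pool of P cycles
    they are uniform on [1, (P-1)*Q] inclusive, so the window starting at
    the largest index ends exactly at sample P*Q.  Pools with more cycles
    contribute proportionally more windows.  Windows never span two pools.
    """
    if isinstance(paired, PairedSignal):
        paired = [paired]
    if R < 0:
        raise ValueError("R must be non-negative")
    if not paired:
        raise ValueError("no pools given")
    for p in paired:
        if p.Q != Q:
            raise ValueError(f"pool cycle length {p.Q} != Q={Q}")
        if p.n_cycles < 2:
            raise ValueError("random truncation needs at least P=2 cycles per pool")
    rng = np.random.default_rng(seed)
    counts = np.array([(p.n_cycles - 1) * Q for p in paired], dtype=float)
    x = np.empty((R, Q))
    y = np.empty((R, Q))
    starts = np.empty(R, dtype=int)
    prov: list[tuple[int, float]] = []
    if R:
        pool_idx = rng.choice(len(paired), size=R, p=counts / counts.sum())
        for i, pi in enumerate(pool_idx):
            p = paired[pi]
            start1 = int(rng.integers(1, (p.n_cycles - 1) * Q + 1))  # 1-based
            s0 = start1 - 1
            x[i] = p.x[s0:s0 + Q]
            y[i] = p.y[s0:s0 + Q]
            starts[i] = start1
            prov.append((p.subject_id, p.level))
    return SampleSet(x=x, y=y, Q=Q, role=role, provenance=prov,
                     starts=starts, seed=seed)


def build_standard_sets(train_pools: list[PairedSignal], dev_pools: list[PairedSignal],
                        test_pools: list[PairedSignal], Q: int,
                        sizes: tuple[int, int, int] = (50_000, 100, 100),
                        seed: int = 0) -> tuple[SampleSet, SampleSet, SampleSet]:
    """Random-truncated sets of the stated sizes (default 50,000/100/100)."""
    ss = np.random.SeedSequence(seed)
    s_tr, s_dev, s_te = (int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(3))
    return (random_truncation(train_pools, Q, sizes[0], seed=s_tr, role="train"),
            random_truncation(dev_pools, Q, sizes[1], seed=s_dev, role="dev"),
            random_truncation(test_pools, Q, sizes[2], seed=s_te, role="test"))


def fixed_pattern_sets(pools: list[PairedSignal], Q: int,
                       role: str = "train") -> SampleSet:
    """One sample per whole contraction cycle — the no-truncation baseline."""
    xs, ys, prov = [], [], []
    for p in pools:
        if p.Q != Q:
            raise ValueError(f"pool cycle length {p.Q} != Q={Q}")
        for c in split_cycles(p):
            xs.append(c.x)
            ys.append(c.y)
            prov.append((p.subject_id, p.level))
    if not xs:
        raise ValueError("no cycles in the pools")
    return SampleSet(x=np.stack(xs), y=np.stack(ys), Q=Q, role=role,
                     provenance=prov, starts=np.empty(0, dtype=int))
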