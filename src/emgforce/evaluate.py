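"""Model scoring and comparison machinery.

Per-sample RMSE% summaries, Bland-Altman limits of agreement between
estimated and measured force, pairwise Kruskal-Wallis tests between model
families, and the two training-strategy contrasts (fixed- vs varied-pattern
and single- vs multi-force training).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .dataset import (Allocation, PairedSignal, SampleSet, allocate,
                      build_standard_sets, fixed_pattern_sets,
                      random_truncation)
from .models import Model, build_model
from .training import TrainConfig, rmse_pct, train_model


@dataclass
class EvaluationReport:
    per_sample_rmse_pct: np.ndarray
    mean: float
    sd: float
    model: str = ""
    circumstance: str = ""
    subject: int | None = None

    @classmethod
    def from_values(cls, values, **labels) -> "EvaluationReport":
        v = np.asarray(values, dtype=float)
        return cls(per_sample_rmse_pct=v, mean=float(v.mean()),
                   sd=float(v.std(ddof=1)) if v.size > 1 else 0.0, **labels)

    def to_dict(self) -> dict:
        return {"per_sample_rmse_pct": self.per_sample_rmse_pct.tolist(),
                "mean": self.mean, "sd": self.sd, "model": self.model,
                "circumstance": self.circumstance, "subject": self.subject}

    @classmethod
    def from_dict(cls, d: dict) -> "EvaluationReport":
        return cls(per_sample_rmse_pct=np.asarray(d["per_sample_rmse_pct"]),
                   mean=d["mean"], sd=d["sd"], model=d["model"],
                   circumstance=d["circumstance"], subject=d["subject"])


@dataclass
class BlandAltmanSummary:
    mean_diff: float
    sd_diff: float
    lower: float
    upper: float
    fraction_within_limits: float


def evaluate_model(model: Model, test: SampleSet, **labels) -> EvaluationReport:
    """RMSE% of every test sample, with mean and standard deviation."""
    if len(test) == 0:
        raise ValueError("empty test set")
    preds = model.forward(test.x, training=False)
    vals = [rmse_pct(test.y[i], preds[i]) for i in range(len(test))]
    return EvaluationReport.from_values(vals, model=model.family, **labels)


def bland_altman(F: np.ndarray, F_hat: np.ndarray) -> BlandAltmanSummary:
    """Limits of agreement for the differences d = F_hat - F."""
    F = np.asarray(F, dtype=float).ravel()
    F_hat = np.asarray(F_hat, dtype=float).ravel()
    if F.size < 2 or F.shape != F_hat.shape:
        raise ValueError("need at least two paired points")
    d = F_hat - F
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    lower, upper = mean - 1.96 * sd, mean + 1.96 * sd
    within = float(np.mean((d >= lower) & (d <= upper)))
    return BlandAltmanSummary(mean, sd, lower, upper, within)


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Rank-based H statistic with tie correction and chi-square p-value.

    The fully-tied degenerate case (every observation identical) returns
    (0, 1) instead of an undefined 0/0 correction.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(g.size == 0 for g in groups):
        raise ValueError("groups must be non-empty")
    allv = np.concatenate(groups)
    if allv.size < 3:
        raise ValueError("need at least three observations in total")
    if np.all(allv == allv[0]):
        return 0.0, 1.0
    H, p = stats.kruskal(*groups)
    return float(H), float(p)


def pairwise_kruskal(reports: dict[str, np.ndarray]) -> dict[tuple[str, str], tuple[float, float]]:
    """Two-group Kruskal-Wallis for every pair of model families."""
    out = {}
    for a, b in itertools.combinations(sorted(reports), 2):
        out[(a, b)] = kruskal_wallis([reports[a], reports[b]])
    return out


@dataclass
class StudyResult:
    reports: dict[str, list[EvaluationReport]]            # family -> per-subject
    pairwise: dict[tuple[str, str], tuple[float, float]]  # (fam, fam) -> (H, p)


def _train_and_score(family: str, alloc: Allocation, Q: int, sizes, cfg: TrainConfig,
                     model_kwargs: dict, circumstance: str) -> list[EvaluationReport]:
    reports = []
    train_set, dev_set, _ = build_standard_sets(
        alloc.train, alloc.dev, alloc.train, Q, sizes=sizes, seed=cfg.seed)
    model = build_model(family, Q, seed=cfg.seed, **model_kwargs.get(family, {}))
    model, _ = train_model(model, train_set, dev_set, cfg)
    for subj, pools in alloc.test.items():
        test_set = random_truncation(pools, Q, sizes[2],
                                     seed=cfg.seed + 7919, role="test")
        reports.append(evaluate_model(model, test_set,
                                      circumstance=circumstance, subject=subj))
    return reports


def run_circumstance_study(signals: list[PairedSignal], circumstance: str,
                           families=("cnn", "lstm", "clstm"),
                           Q: int | None = None,
                           sizes: tuple[int, int, int] = (50_000, 100, 100),
                           cfg: TrainConfig = TrainConfig(),
                           model_kwargs: dict | None = None,
                           seed: int = 0) -> StudyResult:
    """Train every family under one circumstance and compare them.

    For subject_dependent and multi_subject one model per family is trained
    on the (pooled) training data; for subject_independent a leave-one-out
    sweep trains one model per held-out subject.  Pairwise Kruskal-Wallis
    tests are run on the pooled per-sample RMSE% of each family pair.
    """
    model_kwargs = model_kwargs or {}
    Q = Q or signals[0].Q
    subjects = sorted({s.subject_id for s in signals})
    reports: dict[str, list[EvaluationReport]] = {f: [] for f in families}
    for family in families:
        if circumstance == "subject_independent":
            for held_out in subjects:
                alloc = allocate(signals, circumstance, subject=held_out, seed=seed)
                reports[family].extend(_train_and_score(
                    family, alloc, Q, sizes, cfg, model_kwargs, circumstance))
        else:
            subject = subjects[0] if circumstance == "subject_dependent" else None
            alloc = allocate(signals, circumstance, subject=subject, seed=seed)
            reports[family].extend(_train_and_score(
                family, alloc, Q, sizes, cfg, model_kwargs, circumstance))
    pooled = {f: np.concatenate([r.per_sample_rmse_pct for r in reports[f]])
              for f in families}
    return StudyResult(reports=reports, pairwise=pairwise_kruskal(pooled))


@dataclass
class ContrastResult:
    fixed_rmse: dict[str, float]          # family -> mean test RMSE%
    varied_rmse: dict[str, float]
    varied_beats_fixed: dict[str, bool]
    single_force: dict[tuple[str, float, float], float]  # (family, train, test) -> RMSE%
    multi_force: dict[tuple[str, float], float]          # (family, test level) -> RMSE%


def contrast_training_strategies(signals: list[PairedSignal],
                                 families=("cnn", "lstm", "clstm"),
                                 Q: int | None = None,
                                 sizes: tuple[int, int, int] = (50_000, 100, 100),
                                 cfg: TrainConfig = TrainConfig(),
                                 model_kwargs: dict | None = None,
                                 seed: int = 0,
                                 run_force_contrast: bool = True) -> ContrastResult:
    """Fixed- vs varied-pattern and single- vs multi-force training.

    Runs on one subject's data (the first present).  In the fixed-pattern
    arm whole cycles are the training samples; in the varied-pattern arm
    random truncation builds the training set.  Both arms are scored on the
    same randomly-truncated test samples.  The force contrast trains per
    level on 80% of that level's cycles and tests across levels.
    """
    model_kwargs = model_kwargs or {}
    Q = Q or signals[0].Q
    subject = sorted({s.subject_id for s in signals})[0]
    signals = [s for s in signals if s.subject_id == subject]
    alloc = allocate(signals, "subject_dependent", subject=subject, seed=seed)
    test_set = random_truncation(alloc.test[subject], Q, sizes[2],
                                 seed=seed + 7919, role="test")

    fixed_rmse, varied_rmse, beats = {}, {}, {}
    for family in families:
        kw = model_kwargs.get(family, {})
        # fixed-pattern arm: the cycles themselves are the samples
        ftrain = fixed_pattern_sets(alloc.train, Q, role="train")
        fdev = fixed_pattern_sets(alloc.dev, Q, role="dev")
        m = build_model(family, Q, seed=cfg.seed, **kw)
        m, _ = train_model(m, ftrain, fdev, cfg)
        fixed_rmse[family] = evaluate_model(m, test_set).mean
        # varied-pattern arm
        vtrain, vdev, _ = build_standard_sets(alloc.train, alloc.dev, alloc.train,
                                              Q, sizes=sizes, seed=cfg.seed)
        m = build_model(family, Q, seed=cfg.seed, **kw)
        m, _ = train_model(m, vtrain, vdev, cfg)
        varied_rmse[family] = evaluate_model(m, test_set).mean
        beats[family] = varied_rmse[family] < fixed_rmse[family]

    single: dict[tuple[str, float, float], float] = {}
    multi: dict[tuple[str, float], float] = {}
    if run_force_contrast:
        levels = sorted({s.level for s in signals})
        if len(levels) < 3:
            raise ValueError("force contrast needs at least three levels")
        rng = np.random.default_rng(seed)
        per_level: dict[float, dict[str, list[PairedSignal]]] = {}
        for lv in levels:
            lv_sigs = [s for s in signals if s.level == lv]
            a = allocate(lv_sigs, "subject_dependent", subject=subject,
                         seed=int(rng.integers(2 ** 31)))
            per_level[lv] = {"train": a.train, "dev": a.dev,
                             "test": a.test[subject]}
        for family in families:
            kw = model_kwargs.get(family, {})
            test_sets = {lv: random_truncation(per_level[lv]["test"], Q, sizes[2],
                                               seed=seed + 104729, role="test")
                         for lv in levels}
            for lv in levels:
                tr, dv, _ = build_standard_sets(per_level[lv]["train"],
                                                per_level[lv]["dev"],
                                                per_level[lv]["train"],
                                                Q, sizes=sizes, seed=cfg.seed)
                m = build_model(family, Q, seed=cfg.seed, **kw)
                m, _ = train_model(m, tr, dv, cfg)
                for lv_test in levels:
                    single[(family, lv, lv_test)] = evaluate_model(
                        m, test_sets[lv_test]).mean
            # one multi-level model, evaluated on every level's test set
            tr, dv, _ = build_standard_sets(
                [p for lv in levels for p in per_level[lv]["train"]],
                [p for lv in levels for p in per_level[lv]["dev"]],
                alloc.train, Q, sizes=sizes, seed=cfg.seed)
            m = build_model(family, Q, seed=cfg.seed, **kw)
            m, _ = train_model(m, tr, dv, cfg)
            for lv_test in levels:
                multi[(family, lv_test)] = evaluate_model(m, test_sets[lv_test]).mean

    return ContrastResult(fixed_rmse=fixed_rmse, varied_rmse=varied_rmse,
                          varied_beats_fixed=beats, single_force=single,
                          multi_force=multi)
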