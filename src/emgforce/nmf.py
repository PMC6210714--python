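"""NMF-based channel selection for the force-model input signal.

The normalized envelope matrix M (m channels x n samples) is factorized as
M ~ W C with non-negative W (m x s activation patterns / weighting factors)
and C (s x n time-varying coefficients) by Lee-Seung multiplicative updates
on the Frobenius loss, best of several seeded restarts.  The pattern with
the largest activation intensity (row-sum of C) is the major pattern; the
channels whose weighting factors rank in its top quarter are averaged into
the single-channel model input.

The W/C scale ambiguity is resolved by normalizing each W column to unit
sum (compensating in C): the intensity of a pattern then measures the total
activation it explains across all channels, so the major-pattern choice is
invariant to the factorization's arbitrary scaling, and a pattern loaded by
many channels dominates one that only mops up a few noisy electrodes.
Channel ranking within a pattern is unaffected by column scaling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import EnvelopeSet


@dataclass
class ActivationDecomposition:
    W: np.ndarray                 # (m, s) activation patterns, >= 0
    C: np.ndarray                 # (s, n) time-varying coefficients, >= 0
    intensities: np.ndarray       # (s,) row-sums of C
    major_index: int
    selected_channels: np.ndarray  # ordered by descending weighting factor
    reconstruction_error: float   # relative Frobenius error
    error_trajectory: np.ndarray = field(default_factory=lambda: np.empty(0))


def _mu_run(M: np.ndarray, s: int, rng: np.random.Generator,
            tol: float, max_iter: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    m, n = M.shape
    eps = 1e-12
    # uniform (0, 1] initialization
    W = 1.0 - rng.random((m, s))
    C = 1.0 - rng.random((s, n))
    norm_M = np.linalg.norm(M)
    errs = []
    prev = np.inf
    for _ in range(max_iter):
        C *= (W.T @ M) / (W.T @ W @ C + eps)
        W *= (M @ C.T) / (W @ (C @ C.T) + eps)
        err = np.linalg.norm(M - W @ C) / norm_M
        errs.append(err)
        if prev - err < tol:
            break
        prev = err
    return W, C, np.asarray(errs)


def nmf_decompose(M: np.ndarray, s: int = 2, seed: int = 0, n_restarts: int = 5,
                  tol: float = 1e-6, max_iter: int = 500
                  ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Factor M ~ W C; returns (W, C, error_trajectory) of the best restart."""
    M = np.asarray(M, dtype=float)
    if M.ndim != 2:
        raise ValueError("M must be 2-D")
    if np.any(M < 0):
        raise ValueError("M must be non-negative")
    if not np.any(M > 0):
        raise ValueError("M must not be all zero")
    m, n = M.shape
    if not 0 < s < min(m, n):
        raise ValueError(f"rank s={s} must satisfy 0 < s < min(m, n)")
    ss = np.random.SeedSequence(seed)
    best = None
    for child in ss.spawn(n_restarts):
        W, C, errs = _mu_run(M, s, np.random.default_rng(child), tol, max_iter)
        if best is None or errs[-1] < best[2][-1]:
            best = (W, C, errs)
    return best


def normalize_factors(W: np.ndarray, C: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rescale so every W column sums to one; the product W C is unchanged."""
    scale = W.sum(axis=0)
    scale = np.where(scale > 0, scale, 1.0)
    return W / scale, C * scale[:, None]


def activation_intensity(C: np.ndarray) -> np.ndarray:
    """Per-pattern intensity: the sum of its time-varying coefficients."""
    C = np.asarray(C, dtype=float)
    if np.any(C < 0):
        raise ValueError("C must be non-negative")
    return C.sum(axis=-1)


def select_major_pattern(W: np.ndarray, intensities: np.ndarray
                         ) -> tuple[np.ndarray, int]:
    """The pattern of highest intensity; ties broken by lowest index."""
    intensities = np.asarray(intensities)
    if intensities.size == 0:
        raise ValueError("no patterns to select from")
    if W.shape[1] != intensities.size:
        raise ValueError("W columns and intensities disagree")
    idx = int(np.argmax(intensities))     # argmax takes the first maximum
    return W[:, idx], idx


def select_top_channels(w: np.ndarray, fraction: float = 0.25) -> np.ndarray:
    """Indices of the top ``floor(m * fraction)`` weighting factors.

    Ordered by descending weight; ties broken by lower channel index.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    w = np.asarray(w, dtype=float)
    k = int(np.floor(w.size * fraction))
    if k < 1:
        raise ValueError("selection would be empty")
    # stable sort on -w keeps lower indices first among ties
    return np.argsort(-w, kind="stable")[:k]


def average_selected(envelopes: np.ndarray, selected: np.ndarray) -> np.ndarray:
    """Arithmetic mean over the selected channels at each sample."""
    selected = np.asarray(selected, dtype=int)
    if selected.size == 0:
        raise ValueError("empty channel selection")
    return envelopes[selected].mean(axis=0)


def extract_model_input(env_set: EnvelopeSet, s: int = 2, fraction: float = 0.25,
                        seed: int = 0, n_restarts: int = 5, tol: float = 1e-6,
                        max_iter: int = 500, time_stride: int = 1
                        ) -> tuple[np.ndarray, ActivationDecomposition]:
    """Full selection pipeline on one preprocessed recording.

    Returns the averaged single-channel input trace (full resolution) and
    the decomposition details.  ``time_stride`` fits the NMF on every k-th
    sample; envelopes are band-limited to 5 Hz so a stride well below
    fs/10 leaves the spatial factors essentially unchanged while cutting
    the fit cost.
    """
    M = env_set.envelopes[:, ::time_stride]
    W, C, errs = nmf_decompose(M, s=s, seed=seed, n_restarts=n_restarts,
                               tol=tol, max_iter=max_iter)
    Wn, Cn = normalize_factors(W, C)
    intensities = activation_intensity(Cn)
    w_major, major = select_major_pattern(Wn, intensities)
    selected = select_top_channels(w_major, fraction)
    averaged = average_selected(env_set.envelopes, selected)
    decomp = ActivationDecomposition(
        W=Wn, C=Cn, intensities=intensities, major_index=major,
        selected_channels=selected, reconstruction_error=float(errs[-1]),
        error_trajectory=errs)
    return averaged, decomp
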