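"""Reproducibility-optimized test statistic (ROTS).

The statistic family is d(α1, α2) = |x̄₂ − x̄₁| / (α1 + α2·s) with s the
pooled (Tusher) standard error.  The candidate set contains (0, 1)
(t-like), (1, 0) (plain mean difference) and (a, 1) for a on a geometric
grid spanning the central percentiles of s.  For each candidate and each
top-list size k ≤ K, reproducibility is the average overlap proportion of
the top-k gene lists between paired group-preserving bootstrap resamples;
it is standardized against the same quantity under permuted group labels
(Z_k = (R_k − R0_k) / sd(R0_k)), and the (α, k) maximizing Z is selected.
P-values come from the pooled permutation null of the selected statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .sam import _permuted_stats


@dataclass(frozen=True)
class RotsParams:
    B: int = 100
    K: int = 500
    n_alpha: int = 8  # size of the (a, 1) grid
    seed: int = 0
    candidates: tuple[tuple[float, float], ...] | None = None  # explicit (α1, α2) grid

    def __post_init__(self) -> None:
        if self.B < 2:
            raise ConfigurationError(f"B must be >= 2, got {self.B}")
        if self.K < 1:
            raise ConfigurationError(f"K must be >= 1, got {self.K}")


def _candidate_alphas(se: np.ndarray, n_alpha: int) -> list[tuple[float, float]]:
    """(0,1), (1,0) and (a,1) for a geometric over se percentiles."""
    candidates: list[tuple[float, float]] = [(0.0, 1.0), (1.0, 0.0)]
    se = se[np.isfinite(se) & (se > 0)]
    if se.size and n_alpha > 0:
        lo, hi = np.percentile(se, [1, 99])
        lo = max(lo, 1e-8)
        hi = max(hi, lo * (1 + 1e-8))
        for a in np.geomspace(lo, hi, n_alpha):
            candidates.append((float(a), 1.0))
    return candidates


def _stat(diff: np.ndarray, se: np.ndarray, alpha: tuple[float, float]) -> np.ndarray:
    a1, a2 = alpha
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(diff) / (a1 + a2 * se)


def _overlap_profile(d1: np.ndarray, d2: np.ndarray, k_max: int) -> np.ndarray:
    """overlap_k = |top_k(d1) ∩ top_k(d2)| / k for k = 1..k_max.

    Uses the max-rank identity: a gene is in both top-k lists iff the larger
    of its two descending ranks is below k.
    """
    order1 = np.argsort(-d1, kind="stable")
    order2 = np.argsort(-d2, kind="stable")
    rank1 = np.empty_like(order1)
    rank2 = np.empty_like(order2)
    rank1[order1] = np.arange(d1.size)
    rank2[order2] = np.arange(d2.size)
    worst = np.maximum(rank1, rank2)
    counts = np.cumsum(np.bincount(worst, minlength=d1.size))[:k_max]
    return counts / np.arange(1, k_max + 1)


def _bootstrap_columns(n1: int, n2: int, rng: np.random.Generator) -> np.ndarray:
    """Group-preserving bootstrap: resample columns within each group."""
    idx1 = rng.integers(0, n1, size=n1)
    idx2 = n1 + rng.integers(0, n2, size=n2)
    return np.concatenate([idx1, idx2])


def rots_pvalues(
    a: np.ndarray, b: np.ndarray, params: RotsParams
) -> tuple[np.ndarray, dict]:
    """ROTS p-values for (ref, alt) group arrays.

    Returns (p, info) where info records the selected (α1, α2), top-list
    size k and reproducibility Z-score.  Deterministic for a fixed seed.
    """
    n1, n2 = a.shape[1], b.shape[1]
    x = np.concatenate([a, b], axis=1)
    mask = ~np.isnan(x)
    x0 = np.where(mask, x, 0.0)
    n_genes = x.shape[0]
    k_max = min(params.K, n_genes)
    observed_labels = np.array([False] * n1 + [True] * n2)

    diff, se = _permuted_stats(x0, mask, observed_labels[:, None])
    diff, se = diff[:, 0], se[:, 0]
    if params.candidates is not None:
        candidates = [tuple(c) for c in params.candidates]
    else:
        candidates = _candidate_alphas(se, params.n_alpha)

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0x2075)))
    n_cand = len(candidates)
    overlap_boot = np.zeros((n_cand, k_max))
    overlap_null = np.zeros((params.B, n_cand, k_max))

    def stats_for(columns: np.ndarray, labels: np.ndarray):
        sub_mask = mask[:, columns]
        sub_x0 = x0[:, columns]
        d, s = _permuted_stats(sub_x0, sub_mask, labels[:, None])
        return d[:, 0], s[:, 0]

    for bi in range(params.B):
        cols1 = _bootstrap_columns(n1, n2, rng)
        cols2 = _bootstrap_columns(n1, n2, rng)
        d1, s1 = stats_for(cols1, observed_labels)
        d2, s2 = stats_for(cols2, observed_labels)
        perm = rng.permutation(observed_labels)
        cols1n = _bootstrap_columns(n1, n2, rng)
        cols2n = _bootstrap_columns(n1, n2, rng)
        dn1, sn1 = stats_for(cols1n, perm)
        dn2, sn2 = stats_for(cols2n, perm)
        for ci, alpha in enumerate(candidates):
            t1 = np.nan_to_num(_stat(d1, s1, alpha), nan=-np.inf)
            t2 = np.nan_to_num(_stat(d2, s2, alpha), nan=-np.inf)
            overlap_boot[ci] += _overlap_profile(t1, t2, k_max)
            u1 = np.nan_to_num(_stat(dn1, sn1, alpha), nan=-np.inf)
            u2 = np.nan_to_num(_stat(dn2, sn2, alpha), nan=-np.inf)
            overlap_null[bi, ci] = _overlap_profile(u1, u2, k_max)
    overlap_boot /= params.B
    null_mean = overlap_null.mean(axis=0)
    null_sd = overlap_null.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (overlap_boot - null_mean) / null_sd
    z[~np.isfinite(z)] = -np.inf
    ci, ki = np.unravel_index(np.argmax(z), z.shape)
    alpha_star = candidates[ci]

    # pooled permutation null of the selected statistic
    perm_labels = np.stack(
        [rng.permutation(observed_labels) for _ in range(params.B)], axis=1
    )
    diff_p, se_p = _permuted_stats(x0, mask, perm_labels)
    d_null = _stat(diff_p, se_p, alpha_star)
    d_obs = _stat(diff, se, alpha_star)
    from .sam import _pooled_tail_fraction

    null = d_null[np.isfinite(d_null)]
    null.sort()
    p = np.full(n_genes, np.nan)
    finite = np.isfinite(d_obs)
    if null.size:
        p[finite] = _pooled_tail_fraction(null, d_obs[finite])
    else:
        p[finite] = 1.0
    info = {
        "alpha": alpha_star,
        "k": int(ki + 1),
        "z": float(z[ci, ki]),
        "statistic": d_obs,
    }
    return p, info


def rots_test(matrix: pd.DataFrame, groups, pair, params: RotsParams = RotsParams()):
    """Convenience wrapper returning a :class:`~spikebench.diffstats.TestOutcome`."""
    from .diffstats import run_test

    return run_test(matrix, groups, pair, "rots", params=params)
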