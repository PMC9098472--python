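"""Significance analysis of microarrays (SAM), permutation-based.

The per-gene statistic is d = (x̄₂ − x̄₁) / (s + s0), where s is the pooled
(Tusher) standard error and s0 a variance-stabilizing offset ("fudge
factor") chosen from a percentile grid of the gene-wise standard errors so
as to minimize the coefficient of variation of the median absolute
deviation of d across standard-error bins.  Per-gene p-values follow the
pooled-permutation convention: the fraction, over all label permutations
and all genes, of permuted |d*| at least as large as the observed |d|.
When the number of distinct group-label assignments does not exceed the
permutation budget, all assignments are enumerated exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

from .errors import ConfigurationError

DEFAULT_S0_PERCENTILES = tuple(range(0, 101, 5))


@dataclass(frozen=True)
class SamParams:
    n_perm: int = 250
    s0_percentiles: tuple[int, ...] = DEFAULT_S0_PERCENTILES
    seed: int = 0
    s0_override: float | None = None  # force a fudge factor, bypassing selection

    def __post_init__(self) -> None:
        if self.n_perm < 1:
            raise ConfigurationError(f"n_perm must be >= 1, got {self.n_perm}")


def _label_matrix(n1: int, n2: int, n_perm: int, rng: np.random.Generator) -> np.ndarray:
    """Columns are boolean group-2 indicators, one per permutation.

    All C(n1+n2, n2) assignments are enumerated when they fit the budget,
    otherwise ``n_perm`` random label shuffles are drawn.
    """
    n_total = n1 + n2
    n_distinct = comb(n_total, n2)
    if n_distinct < 2:
        raise ConfigurationError("fewer than 2 distinct label permutations possible")
    if n_distinct <= n_perm:
        cols = np.zeros((n_total, n_distinct), dtype=bool)
        for j, idx in enumerate(combinations(range(n_total), n2)):
            cols[list(idx), j] = True
        return cols
    cols = np.zeros((n_total, n_perm), dtype=bool)
    base = np.array([False] * n1 + [True] * n2)
    for j in range(n_perm):
        cols[:, j] = rng.permutation(base)
    return cols


def _permuted_stats(
    x0: np.ndarray, mask: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Per-gene mean difference and Tusher pooled SE for each label column.

    ``x0`` is the combined matrix with missing cells zeroed, ``mask`` the
    observedness indicator and ``labels`` an (n_samples × B) boolean matrix
    marking group 2.  Entries where a permuted group has fewer than two
    observed values are NaN.
    """
    lab = labels.astype(float)
    inv = 1.0 - lab
    n2 = mask @ lab
    n1 = mask @ inv
    s2 = x0 @ lab
    s1 = x0 @ inv
    q2 = (x0**2) @ lab
    q1 = (x0**2) @ inv
    with np.errstate(invalid="ignore", divide="ignore"):
        m1, m2 = s1 / n1, s2 / n2
        ss1 = q1 - n1 * m1**2
        ss2 = q2 - n2 * m2**2
        se = np.sqrt(
            (1.0 / n1 + 1.0 / n2) * (np.maximum(ss1, 0) + np.maximum(ss2, 0)) / (n1 + n2 - 2)
        )
        diff = m2 - m1
    bad = (n1 < 2) | (n2 < 2)
    diff[bad] = np.nan
    se[bad] = np.nan
    return diff, se


def choose_s0(diff: np.ndarray, se: np.ndarray, percentiles=DEFAULT_S0_PERCENTILES) -> float:
    """Tusher-style fudge-factor selection on the observed statistics."""
    ok = np.isfinite(diff) & np.isfinite(se)
    diff, se = diff[ok], se[ok]
    if se.size == 0:
        return 0.0
    grid = np.percentile(se, list(percentiles))
    n_bins = min(100, max(2, se.size // 5))
    edges = np.quantile(se, np.linspace(0, 1, n_bins + 1))
    bins = np.clip(np.searchsorted(edges, se, side="right") - 1, 0, n_bins - 1)
    best_s0, best_cv = float(grid[0]), np.inf
    for s0 in grid:
        with np.errstate(divide="ignore", invalid="ignore"):
            d = diff / (se + s0)
        mads = []
        for b in range(n_bins):
            values = d[(bins == b) & np.isfinite(d)]
            if values.size:
                mads.append(np.median(np.abs(values - np.median(values))))
        mads = np.array(mads)
        if mads.size == 0:
            continue
        mean = mads.mean()
        if mean == 0:
            continue
        cv = mads.std(ddof=0) / mean
        if cv < best_cv:
            best_cv, best_s0 = cv, float(s0)
    return best_s0


def sam_pvalues(
    a: np.ndarray, b: np.ndarray, params: SamParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled-permutation SAM p-values for (ref, alt) group arrays.

    Returns (p, d): the per-gene two-sided p-values and observed statistics.
    Genes with fewer than two observed values in either group are NaN.
    """
    n1, n2 = a.shape[1], b.shape[1]
    x = np.concatenate([a, b], axis=1)
    mask = ~np.isnan(x)
    x0 = np.where(mask, x, 0.0)
    observed_labels = np.array([False] * n1 + [True] * n2)[:, None]
    diff, se = _permuted_stats(x0, mask, observed_labels)
    diff, se = diff[:, 0], se[:, 0]
    if params.s0_override is not None:
        s0 = params.s0_override
    else:
        s0 = choose_s0(diff, se, params.s0_percentiles)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_obs = diff / (se + s0)
    d_obs[np.isnan(se)] = np.nan
    zero_denom = np.isfinite(se) & (se + s0 == 0)
    d_obs[zero_denom & (diff == 0)] = 0.0

    rng = np.random.default_rng(np.random.SeedSequence((params.seed, 0x5A17)))
    labels = _label_matrix(n1, n2, params.n_perm, rng)
    diff_p, se_p = _permuted_stats(x0, mask, labels)
    with np.errstate(invalid="ignore", divide="ignore"):
        d_null = diff_p / (se_p + s0)
    null = np.abs(d_null[np.isfinite(d_null)])
    null.sort()
    p = np.full(d_obs.shape, np.nan)
    finite = np.isfinite(d_obs)
    if null.size:
        p[finite] = _pooled_tail_fraction(null, np.abs(d_obs[finite]))
    else:
        p[finite] = 1.0
    return p, d_obs


def _pooled_tail_fraction(sorted_null: np.ndarray, values: np.ndarray) -> np.ndarray:
    """Fraction of pooled null values >= each observed value.

    Equality is counted with a small relative tolerance: the observed
    labeling is one of the enumerated permutations and must count itself
    despite float jitter between code paths.
    """
    shifted = values - 1e-9 * (1.0 + np.abs(values))
    counts = sorted_null.size - np.searchsorted(sorted_null, shifted, side="left")
    return counts / sorted_null.size


def sam_test(matrix: pd.DataFrame, groups, pair, params: SamParams = SamParams()):
    """Convenience wrapper returning a :class:`~spikebench.diffstats.TestOutcome`."""
    from .diffstats import run_test

    return run_test(matrix, groups, pair, "sam", params=params)
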