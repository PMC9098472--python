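"""Two-group differential-abundance tests and the log2 fold-change estimator.

Seven two-sided tests are available: Student's t (equal variance), Welch's t,
Wilcoxon–Mann–Whitney, a Gamma-family log-link GLM on back-transformed
intensities, an empirical-Bayes moderated t (limma-style variance
shrinkage), SAM (permutation test with a variance-stabilizing offset) and
ROTS (reproducibility-optimized test statistic).  All tests share one
missing-data policy: per-protein computations use observed values only, no
imputation, and proteins with fewer than two observed values in either group
get status ``insufficient_data`` (their p-value is coerced to 1 at
evaluation time).

The estimated log2FC of a protein is the difference of observed-value group
means (second group minus first), undefined if either group is entirely
missing.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import special, stats

from .errors import ConfigurationError

METHODS = ("t_equal", "t_welch", "wilcoxon", "glm_gamma", "limma", "sam", "rots")

STATUS_TESTED = "tested"
STATUS_INSUFFICIENT = "insufficient_data"
STATUS_REMOVED = "removed_by_sr"


@dataclass
class TestOutcome:
    """Per-protein p-values, log2FC estimates and statuses for one test run."""

    table: pd.DataFrame  # index: protein; columns: p_value, log2fc, status
    method: str

    @property
    def p_value(self) -> pd.Series:
        return self.table["p_value"]

    @property
    def log2fc(self) -> pd.Series:
        return self.table["log2fc"]

    @property
    def status(self) -> pd.Series:
        return self.table["status"]

    def effective_p(self) -> pd.Series:
        """p-values with the missing-result coercion applied (p := 1)."""
        p = self.table["p_value"].copy()
        bad = (self.table["status"] != STATUS_TESTED) | p.isna()
        p[bad] = 1.0
        return p

    def with_removed(self, proteins: Sequence[str]) -> "TestOutcome":
        """Append proteins removed upstream (e.g., by sparsity reduction)."""
        if len(proteins) == 0:
            return self
        extra = pd.DataFrame(
            {"p_value": np.nan, "log2fc": np.nan, "status": STATUS_REMOVED},
            index=pd.Index(proteins),
        )
        return TestOutcome(table=pd.concat([self.table, extra]), method=self.method)


# ---------------------------------------------------------------------------
# group handling and basic statistics


def split_groups(
    matrix: pd.DataFrame, groups, pair: tuple[str, str]
) -> tuple[np.ndarray, np.ndarray]:
    """Split a proteins × samples frame into (ref, alt) arrays by group label."""
    labels = np.asarray(groups)
    if labels.shape[0] != matrix.shape[1]:
        raise ConfigurationError(
            f"groups has {labels.shape[0]} entries for {matrix.shape[1]} samples"
        )
    ref, alt = pair
    a = matrix.to_numpy(dtype=float)[:, labels == ref]
    b = matrix.to_numpy(dtype=float)[:, labels == alt]
    if a.shape[1] == 0 or b.shape[1] == 0:
        raise ConfigurationError(f"group pair {pair} not present in group labels")
    return a, b


def _nanstats(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-row observed count, mean and unbiased variance (NaN-aware)."""
    mask = ~np.isnan(x)
    n = mask.sum(axis=1)
    total = np.where(mask, x, 0.0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = total / n
        ssq = np.where(mask, x, 0.0).__pow__(2).sum(axis=1)
        var = (ssq - n * mean**2) / (n - 1)
    var = np.where(n > 1, np.maximum(var, 0.0), np.nan)
    mean = np.where(n > 0, mean, np.nan)
    return n, mean, var


def estimate_log2fc(matrix: pd.DataFrame, groups, pair: tuple[str, str]) -> pd.Series:
    """mean(observed, alt group) − mean(observed, ref group) per protein."""
    a, b = split_groups(matrix, groups, pair)
    _, mean_a, _ = _nanstats(a)
    _, mean_b, _ = _nanstats(b)
    return pd.Series(mean_b - mean_a, index=matrix.index, name="log2fc")


# ---------------------------------------------------------------------------
# parametric tests (vectorised closed forms)


def _p_from_t(t: np.ndarray, df: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return 2.0 * stats.t.sf(np.abs(t), df)


def _resolve_degenerate(p: np.ndarray, diff: np.ndarray, denom: np.ndarray) -> np.ndarray:
    """Zero-variance conventions: equal means → p = 1, unequal → p = 0."""
    zero = denom == 0
    p = np.where(zero & (diff == 0), 1.0, p)
    p = np.where(zero & (diff != 0), 0.0, p)
    return p


def _t_equal(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, m1, v1 = _nanstats(a)
    n2, m2, v2 = _nanstats(b)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
        denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        t = (m2 - m1) / denom
    p = _p_from_t(t, df)
    return _resolve_degenerate(p, m2 - m1, denom)


def _t_welch(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, m1, v1 = _nanstats(a)
    n2, m2, v2 = _nanstats(b)
    with np.errstate(invalid="ignore", divide="ignore"):
        w1, w2 = v1 / n1, v2 / n2
        denom = np.sqrt(w1 + w2)
        t = (m2 - m1) / denom
        df = (w1 + w2) ** 2 / (w1**2 / (n1 - 1) + w2**2 / (n2 - 1))
    p = _p_from_t(t, df)
    return _resolve_degenerate(p, m2 - m1, denom)


def gamma_glm_fit(a: np.ndarray, b: np.ndarray):
    """Closed-form two-group Gamma log-link GLM: (coef, se, df) per gene.

    The coefficient is the log ratio of raw-scale group means (the converged
    IRLS estimate); the standard error uses the Pearson dispersion.
    """
    ya, yb = np.exp2(a), np.exp2(b)
    n1, m1, _ = _nanstats(ya)
    n2, m2, _ = _nanstats(yb)
    with np.errstate(invalid="ignore", divide="ignore"):
        coef = np.log(m2 / m1)
        ra = np.where(~np.isnan(ya), ya / m1[:, None] - 1.0, 0.0)
        rb = np.where(~np.isnan(yb), yb / m2[:, None] - 1.0, 0.0)
        df = n1 + n2 - 2
        phi = (np.sum(ra**2, axis=1) + np.sum(rb**2, axis=1)) / df
        se = np.sqrt(phi * (1.0 / n1 + 1.0 / n2))
    return coef, se, df


def _glm_gamma(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Gamma-family log-link GLM Wald test on raw-scale intensities.

    For a two-group design the IRLS fixed point has fitted means equal to the
    group sample means, giving the group coefficient ``ln(ȳ_alt / ȳ_ref)``
    in closed form.  The dispersion is the Pearson estimate and the Wald
    statistic is referred to a t distribution with n1 + n2 − 2 degrees of
    freedom.
    """
    coef, denom, df = gamma_glm_fit(a, b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t = coef / denom
    p = _p_from_t(t, df)
    return _resolve_degenerate(p, coef, denom)


# ---------------------------------------------------------------------------
# Wilcoxon–Mann–Whitney


@lru_cache(maxsize=64)
def _exact_u_pmf(n1: int, n2: int) -> np.ndarray:
    """Null pmf of the Mann–Whitney U statistic (no ties), by rank-sum DP."""
    n_total = n1 + n2
    max_w = n1 * n_total  # loose upper bound on the rank sum
    f = np.zeros((n1 + 1, max_w + 1))
    f[0, 0] = 1.0
    for rank in range(1, n_total + 1):
        for j in range(min(rank, n1), 0, -1):
            f[j, rank:] += f[j - 1, : max_w + 1 - rank]
    offset = n1 * (n1 + 1) // 2
    pmf = f[n1, offset : offset + n1 * n2 + 1]
    return pmf / pmf.sum()


def _mwu_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann–Whitney p-value.

    Exact enumeration when both groups have ≤ 8 observations and no ties;
    otherwise the normal approximation with tie correction and continuity
    correction.
    """
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = stats.rankdata(combined)
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    u_max = max(u1, n1 * n2 - u1)
    _, tie_counts = np.unique(combined, return_counts=True)
    has_ties = (tie_counts > 1).any()
    if not has_ties and n1 <= 8 and n2 <= 8:
        pmf = _exact_u_pmf(n1, n2)
        p = 2.0 * pmf[int(round(u_max)) :].sum()
        return min(1.0, p)
    n_total = n1 + n2
    tie_term = (tie_counts**3 - tie_counts).sum()
    sigma2 = n1 * n2 / 12.0 * ((n_total + 1) - tie_term / (n_total * (n_total - 1)))
    if sigma2 <= 0:  # all values identical
        return 1.0
    z = (u_max - n1 * n2 / 2.0 - 0.5) / np.sqrt(sigma2)
    return min(1.0, 2.0 * stats.norm.sf(z))


def _wilcoxon(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    p = np.full(a.shape[0], np.nan)
    for g in range(a.shape[0]):
        x = a[g][~np.isnan(a[g])]
        y = b[g][~np.isnan(b[g])]
        if x.size >= 2 and y.size >= 2:
            p[g] = _mwu_p(x, y)
    return p


# ---------------------------------------------------------------------------
# empirical-Bayes moderated t


@dataclass(frozen=True)
class ModeratedTPrior:
    """Inverse-chi-square prior on gene-wise variances: d0 and v0 (= s0²)."""

    d0: float
    v0: float

    def __post_init__(self) -> None:
        if not self.d0 > 0:
            raise ConfigurationError(f"prior degrees of freedom d0 must be > 0, got {self.d0}")
        if not (np.isfinite(self.v0) and self.v0 > 0):
            raise ConfigurationError(f"prior variance v0 must be finite and > 0, got {self.v0}")


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y by Newton iteration (monotone, convex target)."""
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x = x + dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def fit_variance_prior(variances, dfs) -> ModeratedTPrior:
    """Method-of-moments fit of the variance prior on the log scale.

    Matches the first two moments of log sample variances to the scaled-F
    model (digamma/trigamma matching).  When the observed spread of log
    variances does not exceed its expected sampling spread, ``d0 = inf`` and
    ``v0`` is the geometric-mean-based location.
    """
    s2 = np.asarray(variances, dtype=float)
    df = np.broadcast_to(np.asarray(dfs, dtype=float), s2.shape)
    ok = (s2 > 0) & (df > 0) & np.isfinite(s2)
    if not ok.any():
        raise ConfigurationError("all gene-wise variances are zero or undefined")
    s2, df = s2[ok], df[ok]
    if s2.size < 2:
        raise ConfigurationError("need at least 2 genes with positive df and variance")
    e = np.log(s2) - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = e.mean()
    evar = ((e - emean) ** 2).sum() / (e.size - 1) - special.polygamma(1, df / 2.0).mean()
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        v0 = float(np.exp(emean + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        v0 = float(np.exp(emean))
    return ModeratedTPrior(d0=d0, v0=v0)


def moderated_t_pvalues(
    diff: np.ndarray,
    n1: np.ndarray,
    n2: np.ndarray,
    s2: np.ndarray,
    df: np.ndarray,
    prior: ModeratedTPrior,
) -> np.ndarray:
    """Two-sided p-values of the moderated t with shrunken variances."""
    if np.isinf(prior.d0):
        s2_post = np.full_like(np.asarray(s2, dtype=float), prior.v0)
        with np.errstate(invalid="ignore", divide="ignore"):
            t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        return 2.0 * stats.norm.sf(np.abs(t))
    with np.errstate(invalid="ignore", divide="ignore"):
        s2_post = (prior.d0 * prior.v0 + df * s2) / (prior.d0 + df)
        t = diff / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    return _p_from_t(t, prior.d0 + df)


def _limma(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    n1, m1, v1 = _nanstats(a)
    n2, m2, v2 = _nanstats(b)
    df = n1 + n2 - 2
    with np.errstate(invalid="ignore", divide="ignore"):
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    testable = (n1 >= 2) & (n2 >= 2)
    prior = fit_variance_prior(s2[testable], df[testable])
    return moderated_t_pvalues(m2 - m1, n1, n2, s2, df, prior)


# ---------------------------------------------------------------------------
# dispatch


def run_test(
    matrix: pd.DataFrame,
    groups,
    pair: tuple[str, str],
    method: str,
    params=None,
    seed: int | None = None,
) -> TestOutcome:
    """Run one of the seven tests on a proteins × samples frame.

    ``groups`` assigns each column a label; ``pair = (ref, alt)`` selects the
    two compared groups, with log2FC = mean(alt) − mean(ref).  ``params``
    carries :class:`~spikebench.sam.SamParams` /
    :class:`~spikebench.rots.RotsParams` for the permutation tests; ``seed``
    overrides their seed so runs are independently reproducible.
    """
    if method not in METHODS:
        raise ConfigurationError(f"unknown method {method!r}; choose from {METHODS}")
    a, b = split_groups(matrix, groups, pair)
    n1, m1, _ = _nanstats(a)
    n2, m2, _ = _nanstats(b)
    testable = (n1 >= 2) & (n2 >= 2)
    log2fc = np.where((n1 >= 1) & (n2 >= 1), m2 - m1, np.nan)

    import dataclasses

    if method == "t_equal":
        p = _t_equal(a, b)
    elif method == "t_welch":
        p = _t_welch(a, b)
    elif method == "wilcoxon":
        p = _wilcoxon(a, b)
    elif method == "glm_gamma":
        p = _glm_gamma(a, b)
    elif method == "limma":
        p = _limma(a, b)
    elif method == "sam":
        from .sam import SamParams, sam_pvalues

        params = params if params is not None else SamParams()
        if seed is not None:
            params = dataclasses.replace(params, seed=seed)
        p, _ = sam_pvalues(a, b, params)
    else:  # rots
        from .rots import RotsParams, rots_pvalues

        params = params if params is not None else RotsParams()
        if seed is not None:
            params = dataclasses.replace(params, seed=seed)
        p, _ = rots_pvalues(a, b, params)

    p = np.where(testable, p, np.nan)
    status = np.where(testable, STATUS_TESTED, STATUS_INSUFFICIENT)
    table = pd.DataFrame(
        {"p_value": p, "log2fc": log2fc, "status": status}, index=matrix.index
    )
    return TestOutcome(table=table, method=method)
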