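"""Sparsity reduction and normalization of intensity datasets.

The pipeline order is sparsity reduction → normalization → statistical test.
Sparsity reduction filters proteins by the fraction of samples with an
observed quantitation (NoSR / SR66 / SR90).  Four normalizations are
available: none, median (additive re-centering to the grand median),
quantile normalization (QN) against the across-sample mean quantile
function, and tail-robust quantile normalization (TRQN), a QN that builds
its reference from the upper tail of each sample only — robust when the
lower tail is contaminated by intensity-dependent missingness — and shifts
the remaining values by the boundary offset.  All normalizations act on
observed values only and never change the missingness pattern.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .dataio import IntensityDataset
from .errors import ConfigurationError, DataFormatError

SPARSITY_LEVELS = ("NoSR", "SR66", "SR90")
NORMALIZATIONS = ("unnormalized", "median", "QN", "TRQN")
_SR_FRACTION = {"NoSR": 0.0, "SR66": 0.66, "SR90": 0.90}


@dataclass(frozen=True)
class PreprocessOptions:
    """One cell of the sparsity-reduction × normalization grid."""

    sparsity: Literal["NoSR", "SR66", "SR90"] = "NoSR"
    normalization: Literal["unnormalized", "median", "QN", "TRQN"] = "unnormalized"
    trqn_tail_fraction: float = 0.5
    strict_sparsity: bool = False  # use > instead of >= on the observed fraction

    def __post_init__(self) -> None:
        if self.sparsity not in SPARSITY_LEVELS:
            raise ConfigurationError(f"sparsity must be one of {SPARSITY_LEVELS}")
        if self.normalization not in NORMALIZATIONS:
            raise ConfigurationError(f"normalization must be one of {NORMALIZATIONS}")
        if not 0.0 < self.trqn_tail_fraction <= 1.0:
            raise ConfigurationError(
                f"trqn_tail_fraction must be in (0, 1], got {self.trqn_tail_fraction}"
            )


def sparsity_reduce(
    dataset: IntensityDataset,
    level: str,
    strict: bool = False,
) -> tuple[IntensityDataset, list[str]]:
    """Filter proteins by observed-sample fraction.

    Returns the reduced dataset and the list of removed protein ids (recorded
    so that evaluation can coerce their p-values to 1).  ``NoSR`` returns the
    input unchanged.  A protein is kept iff its observed fraction is ``>=``
    (or ``>`` with ``strict=True``) the level's threshold.  The result may
    contain zero proteins; downstream stages must tolerate that.
    """
    if level not in SPARSITY_LEVELS:
        raise ConfigurationError(f"unknown sparsity level {level!r}")
    if level == "NoSR":
        return dataset, []
    threshold = _SR_FRACTION[level]
    fraction = dataset.observed_mask().mean(axis=1)
    keep = fraction > threshold if strict else fraction >= threshold
    removed = dataset.proteins[~keep.to_numpy()].tolist()
    if not removed:
        return dataset, []
    kept = dataset.proteins[keep.to_numpy()]
    reduced = IntensityDataset(
        values=dataset.values.loc[kept].copy(),
        species=dataset.species.loc[kept].copy(),
        condition=dataset.condition.copy(),
    )
    return reduced, removed


def _sample_quantile_knots(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sorted observed values with mid-rank quantile levels (r - 0.5)/m."""
    obs = np.sort(values[~np.isnan(values)])
    m = obs.size
    levels = (np.arange(1, m + 1) - 0.5) / m
    return levels, obs


def _reference_quantile(columns: list[tuple[np.ndarray, np.ndarray]]):
    """Across-sample mean of per-sample empirical quantile functions."""

    def ref(u: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(u, dtype=float)
        for levels, obs in columns:
            acc += np.interp(u, levels, obs)
        return acc / len(columns)

    return ref


def _midrank_levels(values: np.ndarray) -> np.ndarray:
    """Per-cell quantile level (rank - 0.5)/m with average ranks for ties."""
    mask = ~np.isnan(values)
    m = int(mask.sum())
    levels = np.full(values.shape, np.nan)
    levels[mask] = (rankdata(values[mask], method="average") - 0.5) / m
    return levels


def _normalize_median(values: pd.DataFrame) -> pd.DataFrame:
    medians = values.median(axis=0, skipna=True)
    grand = medians.median()
    return values - medians + grand


def _normalize_qn(values: pd.DataFrame) -> pd.DataFrame:
    arr = values.to_numpy(dtype=float)
    knots = [_sample_quantile_knots(arr[:, j]) for j in range(arr.shape[1])]
    ref = _reference_quantile(knots)
    out = np.full(arr.shape, np.nan)
    for j in range(arr.shape[1]):
        levels = _midrank_levels(arr[:, j])
        mask = ~np.isnan(levels)
        out[mask, j] = ref(levels[mask])
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def _normalize_trqn(values: pd.DataFrame, q: float) -> pd.DataFrame:
    """QN built from the top q fraction of each sample's observed values.

    Observed values at or above the per-sample (1 - q)-quantile are mapped by
    quantile normalization against a reference built from tail values only
    (at their full-sample quantile levels); values below the cut are shifted
    additively by the offset the mapping applies at the cut, keeping the
    per-sample transform continuous and monotone.
    """
    arr = values.to_numpy(dtype=float)
    n_samples = arr.shape[1]
    cut_level = 1.0 - q
    tail_knots = []
    cuts = np.empty(n_samples)
    for j in range(n_samples):
        obs = arr[:, j][~np.isnan(arr[:, j])]
        cuts[j] = np.quantile(obs, cut_level)
        levels, ordered = _sample_quantile_knots(arr[:, j])
        in_tail = ordered >= cuts[j]
        tail_knots.append((levels[in_tail], ordered[in_tail]))
    ref = _reference_quantile(tail_knots)
    out = np.full(arr.shape, np.nan)
    for j in range(n_samples):
        col = arr[:, j]
        levels = _midrank_levels(col)
        obs_mask = ~np.isnan(col)
        tail_mask = obs_mask & (col >= cuts[j])
        below_mask = obs_mask & ~tail_mask
        out[tail_mask, j] = ref(levels[tail_mask])
        if below_mask.any():
            # offset at the boundary: where the sample's smallest tail value maps
            tail_values = col[tail_mask]
            anchor = tail_values.min()
            anchor_level = levels[tail_mask][tail_values.argmin()]
            offset = ref(np.array([anchor_level]))[0] - anchor
            out[below_mask, j] = col[below_mask] + offset
    return pd.DataFrame(out, index=values.index, columns=values.columns)


def normalize(dataset: IntensityDataset, options: PreprocessOptions) -> IntensityDataset:
    """Apply the selected normalization; missing cells stay missing."""
    values = dataset.values
    empty = values.notna().sum(axis=0) == 0
    if empty.any():
        raise DataFormatError(
            f"sample(s) with zero observed values: {values.columns[empty].tolist()[:5]}"
        )
    if options.normalization == "unnormalized":
        return dataset
    if options.normalization == "median":
        normalized = _normalize_median(values)
    elif options.normalization == "QN":
        normalized = _normalize_qn(values)
    else:
        normalized = _normalize_trqn(values, options.trqn_tail_fraction)
    return IntensityDataset(
        values=normalized, species=dataset.species.copy(), condition=dataset.condition.copy()
    )


def preprocess(
    dataset: IntensityDataset, options: PreprocessOptions
) -> tuple[IntensityDataset, list[str]]:
    """Sparsity reduction followed by normalization; returns removed proteins."""
    reduced, removed = sparsity_reduce(dataset, options.sparsity, options.strict_sparsity)
    if reduced.n_proteins == 0:
        return reduced, removed
    return normalize(reduced, options), removed
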