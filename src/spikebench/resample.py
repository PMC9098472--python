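"""Bootstrap experimental design and per-bootstrap data characteristics.

The benchmark draws, for every group size n in an inclusive range and every
replicate, n samples with replacement from each of the two compared spike-in
conditions; each (size, replicate) cell carries a seed derived
deterministically from the base seed so the whole design is reproducible
end-to-end and any subset can be recomputed in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import IntensityDataset
from .errors import ConfigurationError
from .synthdata import DEFAULT_PAIR


@dataclass(frozen=True)
class BootstrapDesign:
    min_size: int = 3
    max_size: int = 23
    replicates: int = 100
    base_seed: int = 0
    pair: tuple[str, str] = DEFAULT_PAIR

    def __post_init__(self) -> None:
        if self.min_size < 2:
            raise ConfigurationError(f"min_size must be >= 2, got {self.min_size}")
        if self.max_size < self.min_size:
            raise ConfigurationError(
                f"empty size range [{self.min_size}, {self.max_size}]"
            )
        if self.replicates < 1:
            raise ConfigurationError(f"replicates must be >= 1, got {self.replicates}")

    @property
    def sizes(self) -> range:
        return range(self.min_size, self.max_size + 1)


@dataclass(frozen=True)
class BootstrapEntry:
    n: int
    replicate: int
    seed: int


@dataclass
class BootstrapDataset:
    """A materialized two-group bootstrap draw.

    Duplicated source samples appear as duplicated (uniquely renamed)
    columns, per standard bootstrap semantics.
    """

    matrix: pd.DataFrame
    groups: np.ndarray  # condition label per column
    drawn: dict[str, list[str]]  # condition -> drawn source sample ids (multiset)
    n: int
    replicate: int
    seed: int
    pair: tuple[str, str] = DEFAULT_PAIR


def derive_seed(base_seed: int, n: int, replicate: int) -> int:
    """Stable sub-seed for one design cell (fits in 32 bits)."""
    return int(np.random.SeedSequence((base_seed, n, replicate)).generate_state(1)[0])


def enumerate_design(design: BootstrapDesign) -> list[BootstrapEntry]:
    """One entry per (group size, replicate), in deterministic order."""
    return [
        BootstrapEntry(n=n, replicate=r, seed=derive_seed(design.base_seed, n, r))
        for n in design.sizes
        for r in range(design.replicates)
    ]


def draw_bootstrap(
    dataset: IntensityDataset,
    entry: BootstrapEntry,
    pair: tuple[str, str] = DEFAULT_PAIR,
) -> BootstrapDataset:
    """Draw n samples with replacement from each condition of the pair."""
    rng = np.random.default_rng(entry.seed)
    blocks = []
    labels = []
    drawn: dict[str, list[str]] = {}
    for cond in pair:
        source = dataset.samples_of(cond)
        if len(source) == 0:
            raise ConfigurationError(f"condition {cond!r} absent from dataset")
        picks = rng.integers(0, len(source), size=entry.n)
        ids = [source[i] for i in picks]
        drawn[cond] = ids
        block = dataset.values[ids].copy()
        block.columns = [f"{sid}.b{j}" for j, sid in enumerate(ids)]
        blocks.append(block)
        labels.extend([cond] * entry.n)
    matrix = pd.concat(blocks, axis=1)
    return BootstrapDataset(
        matrix=matrix,
        groups=np.array(labels),
        drawn=drawn,
        n=entry.n,
        replicate=entry.replicate,
        seed=entry.seed,
        pair=pair,
    )


@dataclass
class DataCharacteristics:
    """Moment summaries of a two-group bootstrap matrix (observed values)."""

    median_protein_variance: dict[str, float]
    variance_ratio: float  # group2 / group1 median protein variance
    skewness: float
    kurtosis: float  # excess kurtosis
    missing_fraction: float
    defined: bool = True


def data_characteristics(bootstrap: BootstrapDataset) -> DataCharacteristics:
    """Sample variance, skewness, excess kurtosis, variance ratio, missingness.

    Moments are computed on all observed log2 values pooled; protein
    variances use the n−1 denominator per group.
    """
    matrix = bootstrap.matrix
    arr = matrix.to_numpy(dtype=float)
    observed = arr[~np.isnan(arr)]
    missing_fraction = float(np.isnan(arr).mean())
    med_var: dict[str, float] = {}
    defined = True
    for cond in bootstrap.pair:
        cols = bootstrap.groups == cond
        sub = arr[:, cols]
        if (~np.isnan(sub)).sum() < 2:
            med_var[cond] = np.nan
            defined = False
            continue
        with np.errstate(invalid="ignore"):
            protein_var = pd.DataFrame(sub).var(axis=1, ddof=1, skipna=True)
        med_var[cond] = float(protein_var.median(skipna=True))
    g1, g2 = bootstrap.pair
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = (
            np.float64(med_var[g2]) / np.float64(med_var[g1]) if defined else np.nan
        )
    if observed.size >= 2 and np.var(observed) > 0:
        skew = float(stats.skew(observed, bias=True))
        kurt = float(stats.kurtosis(observed, fisher=True, bias=True))
    else:
        skew, kurt, defined = np.nan, np.nan, False
    return DataCharacteristics(
        median_protein_variance=med_var,
        variance_ratio=float(ratio) if np.isfinite(ratio) else np.nan,
        skewness=skew,
        kurtosis=kurt,
        missing_fraction=missing_fraction,
        defined=defined,
    )
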