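"""Reading, validation, harmonization and writing of intensity datasets.

The common in-memory container is :class:`IntensityDataset`: a proteins ×
samples matrix of log2 intensities (``NaN`` marks a missing quantitation)
together with a per-protein species label and a per-sample spike-in condition.
Species is carried by Swiss-Prot style entry-name suffixes (``…_HUMAN``,
``…_ECOLI``); identifiers composed of several entry names are classified by
unanimity and otherwise flagged ambiguous.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import AnnotationError, DataFormatError

logger = logging.getLogger(__name__)

HUMAN = "human"
ECOLI = "ecoli"
AMBIGUOUS = "ambiguous"

#: Default mapping from entry-name suffix to species label.
DEFAULT_SUFFIXES: Mapping[str, str] = {"_HUMAN": HUMAN, "_ECOLI": ECOLI}


@dataclass(frozen=True)
class DialectOptions:
    """Settings describing how a tabular intensity file is encoded.

    Parameters
    ----------
    sep
        Field separator.
    log2
        If True the file already stores log2 intensities; if False it stores
        raw intensities, values ``<= 0`` are treated as missing and the rest
        are log2-transformed on read.
    na_codes
        Strings interpreted as a missing quantitation.
    zero_is_missing
        Treat literal ``0`` cells as missing (software suites differ in how
        they encode absent quantitations).
    entry_separator
        Separator joining multiple entry names inside one protein identifier.
    """

    sep: str = "\t"
    log2: bool = True
    na_codes: tuple[str, ...] = ("", "NA", "NaN", "nan")
    zero_is_missing: bool = True
    entry_separator: str = ";"


def parse_species(
    entry_name: str,
    entry_separator: str = ";",
    suffixes: Mapping[str, str] = DEFAULT_SUFFIXES,
) -> str:
    """Classify a protein identifier as ``human``, ``ecoli`` or ``ambiguous``.

    Compound identifiers (several entry names joined by ``entry_separator``)
    are classified by unanimity: every member must map to the same species,
    otherwise the identifier is ambiguous.  Identifiers with an unknown
    suffix are ambiguous as well.
    """
    if not entry_name or not str(entry_name).strip():
        raise DataFormatError("empty protein entry name")
    parts = [p.strip() for p in str(entry_name).split(entry_separator)]
    labels = set()
    for part in parts:
        if not part:
            raise DataFormatError(f"empty component in entry name {entry_name!r}")
        for suffix, label in suffixes.items():
            if part.endswith(suffix):
                labels.add(label)
                break
        else:
            labels.add(AMBIGUOUS)
    if len(labels) == 1:
        return labels.pop()
    return AMBIGUOUS


@dataclass
class IntensityDataset:
    """Proteins × samples log2 intensity matrix with species and conditions.

    ``values`` is indexed by protein entry name with one column per sample id;
    ``NaN`` marks missing quantitations.  ``species`` maps protein → species
    label and ``condition`` maps sample id → spike-in condition.
    """

    values: pd.DataFrame
    species: pd.Series
    condition: pd.Series

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate protein ids: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataFormatError(f"duplicate sample ids: {dups[:5]}")
        self.species = self.species.reindex(self.values.index)
        if self.species.isna().any():
            missing = self.species.index[self.species.isna()].tolist()
            raise DataFormatError(f"proteins without species label: {missing[:5]}")
        try:
            self.condition = self.condition.reindex(self.values.columns)
        except Exception as exc:  # unalignable annotation
            raise AnnotationError(str(exc)) from exc
        if self.condition.isna().any():
            missing = self.condition.index[self.condition.isna()].tolist()
            raise AnnotationError(f"samples without condition annotation: {missing[:5]}")
        arr = self.values.to_numpy(dtype=float)
        if np.isinf(arr).any():
            raise DataFormatError("non-finite intensity values present")

    # -- convenience accessors -------------------------------------------------

    @property
    def proteins(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_proteins(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def observed_mask(self) -> pd.DataFrame:
        """Boolean frame, True where a quantitation is present."""
        return self.values.notna()

    def samples_of(self, condition: str) -> pd.Index:
        return self.condition.index[self.condition == condition]

    def subset(
        self,
        proteins: Iterable[str] | None = None,
        samples: Iterable[str] | None = None,
    ) -> "IntensityDataset":
        values = self.values
        if proteins is not None:
            values = values.loc[list(proteins)]
        if samples is not None:
            values = values[list(samples)]
        return IntensityDataset(
            values=values.copy(),
            species=self.species.loc[values.index].copy(),
            condition=self.condition.loc[values.columns].copy(),
        )

    def copy(self) -> "IntensityDataset":
        return IntensityDataset(
            self.values.copy(), self.species.copy(), self.condition.copy()
        )


def read_annotation(
    source: str | Path | IO[str] | pd.DataFrame | pd.Series | Mapping[str, str],
    sep: str = "\t",
) -> pd.Series:
    """Read a sample annotation (sample id → condition).

    Tabular sources need columns ``sample`` and ``condition``; an optional
    boolean/0-1 ``exclude`` column drops corrupted samples from the analysis
    (the generalized form of excluding individual damaged recordings).
    """
    if isinstance(source, pd.Series):
        ann = source.copy()
    elif isinstance(source, Mapping):
        ann = pd.Series(dict(source))
    else:
        if isinstance(source, pd.DataFrame):
            table = source
        else:
            table = pd.read_csv(source, sep=sep, dtype=str)
        required = {"sample", "condition"}
        if not required.issubset(table.columns):
            raise AnnotationError(
                f"annotation needs columns {sorted(required)}, got {list(table.columns)}"
            )
        excluded: list[str] = []
        if "exclude" in table.columns:
            flag = table["exclude"].astype(str).str.lower().isin(("1", "true", "yes"))
            excluded = table.loc[flag, "sample"].tolist()
            if excluded:
                logger.info("excluding %d annotated samples", len(excluded))
            table = table[~flag]
        ann = table.set_index("sample")["condition"]
        ann.attrs["excluded"] = excluded
    if ann.index.has_duplicates:
        raise AnnotationError("duplicate sample ids in annotation")
    return ann


def read_intensity_matrix(
    source: str | Path | IO[str],
    annotation: str | Path | IO[str] | pd.DataFrame | pd.Series | Mapping[str, str],
    options: DialectOptions = DialectOptions(),
) -> IntensityDataset:
    """Read a delimited intensity matrix into an :class:`IntensityDataset`.

    The first column must hold protein entry names; remaining columns are
    samples.  Values are returned on the log2 scale (``options.log2`` declares
    whether the file is already log2 or raw; raw values ``<= 0`` become
    missing before transformation).
    """
    table = pd.read_csv(
        source,
        sep=options.sep,
        na_values=list(options.na_codes),
        keep_default_na=False,
        index_col=0,
    )
    values = table.astype(float)
    if options.zero_is_missing:
        values = values.where(values != 0.0)
    if not options.log2:
        values = values.where(values > 0.0)
        values = np.log2(values)
    values.index.name = None
    ann = read_annotation(annotation, sep=options.sep)
    excluded = set(ann.attrs.get("excluded", ()))
    if excluded:
        values = values[[s for s in values.columns if s not in excluded]]
    unknown = values.columns.difference(ann.index)
    if len(unknown):
        raise AnnotationError(
            f"samples present in matrix but absent from annotation: {list(unknown)[:5]}"
        )
    # samples excluded via annotation are dropped from the matrix
    values = values[[s for s in values.columns if s in ann.index]]
    species = pd.Series(
        {p: parse_species(p, options.entry_separator) for p in values.index},
        name="species",
    )
    return IntensityDataset(values=values, species=species, condition=ann.loc[values.columns])


def write_intensity_matrix(
    dataset: IntensityDataset, path: str | Path | IO[str], sep: str = "\t"
) -> None:
    """Write the matrix as delimited text; missing cells become empty fields."""
    out = dataset.values.copy()
    out.index.name = "protein"
    out.to_csv(path, sep=sep, na_rep="")


def write_annotation(
    dataset: IntensityDataset, path: str | Path | IO[str], sep: str = "\t"
) -> None:
    table = pd.DataFrame(
        {"sample": dataset.samples, "condition": dataset.condition.to_numpy()}
    )
    table.to_csv(path, sep=sep, index=False)


def write_ground_truth(truth, path: str | Path | IO[str], sep: str = "\t") -> None:
    """Write a ground-truth manifest (protein, species, true_log2fc, present_in)."""
    table = pd.DataFrame(
        {
            "protein": truth.species.index,
            "species": truth.species.to_numpy(),
            "true_log2fc": truth.true_log2fc.reindex(truth.species.index).to_numpy(),
            "present_in": [
                ";".join(sorted(truth.present_in[p])) for p in truth.species.index
            ],
        }
    )
    table.to_csv(path, sep=sep, index=False)


def harmonize(dataset: IntensityDataset) -> IntensityDataset:
    """Apply the common-format harmonization rules.

    Ambiguous-species proteins (labeled both human and E. coli, or carrying
    unknown suffixes) are excluded and proteins without any reported
    quantitation are removed.  Idempotent; removal counts are logged.
    """
    ambiguous = dataset.species == AMBIGUOUS
    all_missing = ~dataset.observed_mask().any(axis=1)
    drop = ambiguous | all_missing
    n_ambiguous = int(ambiguous.sum())
    n_empty = int((all_missing & ~ambiguous).sum())
    if n_ambiguous or n_empty:
        logger.info(
            "harmonize: removed %d ambiguous-species and %d all-missing proteins",
            n_ambiguous,
            n_empty,
        )
    keep = dataset.proteins[~drop.to_numpy()]
    if len(keep) == 0:
        raise DataFormatError("no proteins remain after harmonization")
    if not drop.any():
        return dataset
    return dataset.subset(proteins=keep)
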