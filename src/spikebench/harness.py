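"""Factorial benchmark harness.

Runs workflows × sparsity reduction × normalization × statistical tests over
a bootstrap design and scores every combination against the requested
reference protein lists.  Rows are independent work units keyed by
(workflow, bootstrap cell, options); results are emitted in deterministic
order and are bit-reproducible from the base seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import IntensityDataset
from .diffstats import METHODS, run_test
from .errors import ConfigurationError, SpikebenchError
from .evaluate import build_reference_lists, evaluate_outcome
from .preprocess import PreprocessOptions, normalize, sparsity_reduce
from .resample import (
    BootstrapDesign,
    data_characteristics,
    derive_seed,
    draw_bootstrap,
    enumerate_design,
)
from .synthdata import GroundTruth, WorkflowEnsemble

logger = logging.getLogger(__name__)

KEY_COLUMNS = ["workflow", "sparsity", "normalization", "test", "n", "replicate", "reference"]
METRIC_COLUMNS = ["pauc", "sensitivity", "rmse"]


@dataclass
class GridSpec:
    """The full option grid of one benchmark run."""

    workflows: Mapping[str, IntensityDataset]
    truth: GroundTruth
    design: BootstrapDesign
    sparsity_levels: Sequence[str] = ("NoSR", "SR66", "SR90")
    normalizations: Sequence[str] = ("unnormalized", "median", "QN", "TRQN")
    tests: Sequence[str] = ("t_equal", "t_welch", "wilcoxon", "glm_gamma", "limma", "sam", "rots")
    references: Sequence[str] = ("workflow",)
    intersection_threshold: float = 0.8
    fpr_max: float = 0.1
    alpha: float = 0.05
    test_params: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("workflows", "sparsity_levels", "normalizations", "tests", "references"):
            if len(getattr(self, name)) == 0:
                raise ConfigurationError(f"{name} must be non-empty")

    @classmethod
    def from_ensemble(cls, ensemble: WorkflowEnsemble, design: BootstrapDesign, **kwargs):
        return cls(
            workflows=dict(ensemble.members), truth=ensemble.truth, design=design, **kwargs
        )


def count_combinations(spec: GridSpec) -> tuple[int, int]:
    """(workflow-level combination count, case count incl. bootstraps).

    Pure arithmetic: |workflows| · |sparsity| · |normalizations| · |tests|,
    and that times the number of bootstrap datasets.
    """
    workflow_level = (
        len(spec.workflows)
        * len(spec.sparsity_levels)
        * len(spec.normalizations)
        * len(spec.tests)
    )
    n_bootstrap = len(spec.design.sizes) * spec.design.replicates
    return workflow_level, workflow_level * n_bootstrap


def _evaluate_all(outcome, spec: GridSpec, references, workflow_label: str):
    per_reference = []
    for ref_name in spec.references:
        ref_set = references.get(ref_name, workflow=workflow_label)
        result = evaluate_outcome(
            outcome,
            spec.truth,
            ref_set,
            reference_name=ref_name,
            fpr_max=spec.fpr_max,
            alpha=spec.alpha,
        )
        per_reference.append(result)
    return per_reference


def run_grid(
    spec: GridSpec,
    base_seed: int | None = None,
    existing: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Execute the full grid; returns one row per key tuple × reference list.

    Per-row failures are recorded in the ``status`` column
    (``preprocessing_empty``, ``test_failure``) instead of aborting the run.
    ``existing`` rows (matched on the key columns) are skipped, making
    execution resumable.
    """
    base_seed = spec.design.base_seed if base_seed is None else base_seed
    references = build_reference_lists(
        {label: set(ds.proteins) for label, ds in spec.workflows.items()},
        threshold=spec.intersection_threshold,
    )
    done: set[tuple] = set()
    rows: list[dict] = []
    if existing is not None and len(existing):
        done = set(map(tuple, existing[KEY_COLUMNS].itertuples(index=False, name=None)))
        rows.extend(existing.to_dict("records"))
    entries = enumerate_design(
        BootstrapDesign(
            min_size=spec.design.min_size,
            max_size=spec.design.max_size,
            replicates=spec.design.replicates,
            base_seed=base_seed,
            pair=spec.design.pair,
        )
    )
    for workflow_label, dataset in spec.workflows.items():
        for entry in entries:
            bootstrap = draw_bootstrap(dataset, entry, spec.design.pair)
            chars = data_characteristics(bootstrap)
            boot_ds = IntensityDataset(
                values=bootstrap.matrix,
                species=dataset.species.copy(),
                condition=pd.Series(bootstrap.groups, index=bootstrap.matrix.columns),
            )
            for sparsity in spec.sparsity_levels:
                reduced, removed = sparsity_reduce(boot_ds, sparsity)
                for norm in spec.normalizations:
                    if reduced.n_proteins == 0:
                        normalized = reduced
                    else:
                        normalized = normalize(
                            reduced, PreprocessOptions(sparsity="NoSR", normalization=norm)
                        )
                    for test in spec.tests:
                        key_base = (workflow_label, sparsity, norm, test, entry.n, entry.replicate)
                        if done and all(
                            key_base + (ref,) in done for ref in spec.references
                        ):
                            continue
                        # stable per-(bootstrap, method) stream: str hash is salted,
                        # so key the method by its registry position
                        test_seed = derive_seed(entry.seed, METHODS.index(test), 0)
                        try:
                            outcome = run_test(
                                normalized.values,
                                bootstrap.groups,
                                spec.design.pair,
                                test,
                                params=spec.test_params.get(test),
                                seed=test_seed,
                            ).with_removed(removed)
                            status = "ok" if reduced.n_proteins else "preprocessing_empty"
                            results = _evaluate_all(outcome, spec, references, workflow_label)
                        except SpikebenchError as exc:
                            logger.warning("row %s failed: %s", key_base, exc)
                            status, results = "test_failure", []
                        if results:
                            for res in results:
                                rows.append(
                                    {
                                        "workflow": workflow_label,
                                        "sparsity": sparsity,
                                        "normalization": norm,
                                        "test": test,
                                        "n": entry.n,
                                        "replicate": entry.replicate,
                                        "reference": res.reference,
                                        "status": status,
                                        "pauc": res.pauc,
                                        "sensitivity": res.sensitivity,
                                        "rmse": res.rmse,
                                        "tp": res.tp,
                                        "fp": res.fp,
                                        "tn": res.tn,
                                        "fn": res.fn,
                                        "max_tpr": res.max_tpr,
                                        "missing_fraction": chars.missing_fraction,
                                        "variance_ratio": chars.variance_ratio,
                                        "skewness": chars.skewness,
                                        "kurtosis": chars.kurtosis,
                                    }
                                )
                        else:
                            for ref in spec.references:
                                rows.append(
                                    {
                                        "workflow": workflow_label,
                                        "sparsity": sparsity,
                                        "normalization": norm,
                                        "test": test,
                                        "n": entry.n,
                                        "replicate": entry.replicate,
                                        "reference": ref,
                                        "status": status,
                                        "pauc": np.nan,
                                        "sensitivity": np.nan,
                                        "rmse": np.nan,
                                        "tp": 0,
                                        "fp": 0,
                                        "tn": 0,
                                        "fn": 0,
                                        "max_tpr": np.nan,
                                        "missing_fraction": chars.missing_fraction,
                                        "variance_ratio": chars.variance_ratio,
                                        "skewness": chars.skewness,
                                        "kurtosis": chars.kurtosis,
                                    }
                                )
    table = pd.DataFrame(rows)
    return table.sort_values(KEY_COLUMNS, kind="stable").reset_index(drop=True)


def summarize(rows: pd.DataFrame, by: Sequence[str]) -> pd.DataFrame:
    """Median and quartiles of the metrics per group, with best-option flags.

    The best option per reference list (maximal median pAUC) is flagged in
    ``best_pauc``.
    """
    if len(rows) == 0:
        raise ConfigurationError("summarize needs a non-empty result table")
    by = list(by)
    grouped = rows.groupby(by, dropna=False)
    pieces = {}
    for metric in METRIC_COLUMNS:
        pieces[f"{metric}_median"] = grouped[metric].median()
        pieces[f"{metric}_q1"] = grouped[metric].quantile(0.25)
        pieces[f"{metric}_q3"] = grouped[metric].quantile(0.75)
    summary = pd.DataFrame(pieces).reset_index()
    summary["best_pauc"] = False
    if "reference" in by:
        flag_scope = [c for c in ["reference"] if c in by]
        for _, idx in summary.groupby(flag_scope).groups.items():
            best = summary.loc[idx, "pauc_median"].idxmax()
            summary.loc[best, "best_pauc"] = True
    else:
        summary.loc[summary["pauc_median"].idxmax(), "best_pauc"] = True
    return summary
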