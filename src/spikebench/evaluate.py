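"""Reference protein lists and performance measures.

Three reference lists are supported: the per-workflow list (the proteins a
workflow reports), the 'Combined' list (union over all workflows), and the
'Intersection' list (proteins appearing in more than a threshold fraction —
default 80% — of the workflows).  Against a reference list and the known
ground truth, every test outcome is scored by:

* scaled partial AUC — the area under the ROC curve restricted to false
  positive rates ≤ 10%, rescaled so the best reachable value is 100;
* sensitivity at significance level α = 0.05;
* the root-mean-square error of the estimated versus true log2FC.

Positives are spike proteins of the reference list, negatives human
proteins.  Proteins of the reference absent from the outcome are treated as
never called (they cap the maximum reachable TPR); proteins present with a
missing p-value count as p = 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .dataio import ECOLI, HUMAN, IntensityDataset
from .diffstats import TestOutcome
from .errors import ConfigurationError
from .synthdata import GroundTruth


@dataclass
class ReferenceLists:
    per_workflow: dict[str, set[str]]
    combined: set[str]
    intersection: set[str]
    threshold: float

    def get(self, name: str, workflow: str | None = None) -> set[str]:
        if name == "combined":
            return self.combined
        if name == "intersection":
            return self.intersection
        if name == "workflow":
            if workflow is None:
                raise ConfigurationError("workflow reference list needs a workflow label")
            return self.per_workflow[workflow]
        raise ConfigurationError(f"unknown reference list {name!r}")


def build_reference_lists(
    workflow_sets: Mapping[str, Iterable[str]], threshold: float = 0.8
) -> ReferenceLists:
    """Union and >threshold-membership lists over per-workflow protein sets.

    The intersection's minimum membership count is ``floor(threshold · W) + 1``
    (strictly more than the threshold fraction), e.g. at least 14 of 17
    workflows for the default threshold of 0.8.
    """
    sets = {label: set(s) for label, s in workflow_sets.items()}
    if not sets:
        raise ConfigurationError("empty workflow ensemble")
    n_workflows = len(sets)
    min_count = int(np.floor(threshold * n_workflows)) + 1
    counts: dict[str, int] = {}
    for members in sets.values():
        for protein in members:
            counts[protein] = counts.get(protein, 0) + 1
    combined = set(counts)
    intersection = {p for p, c in counts.items() if c >= min_count}
    return ReferenceLists(
        per_workflow=sets, combined=combined, intersection=intersection, threshold=threshold
    )


@dataclass
class RocCurve:
    """Vertex-collapsed ROC polyline anchored at (0, 0).

    ``max_tpr`` < 1 when reference proteins are absent from the outcome
    (never-called positives cap the curve).
    """

    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray  # p-value threshold per vertex (NaN for the anchor)

    @property
    def max_tpr(self) -> float:
        return float(self.tpr[-1]) if self.tpr.size else 0.0


def _reference_species(truth: GroundTruth, reference: Iterable[str]):
    ref = pd.Index(sorted(reference))
    if len(ref) == 0:
        raise ConfigurationError("empty reference protein list")
    species = truth.species.reindex(ref)
    if species.isna().any():
        missing = ref[species.isna()].tolist()
        raise ConfigurationError(f"reference proteins missing from ground truth: {missing[:5]}")
    pos = ref[(species == ECOLI).to_numpy()]
    neg = ref[(species == HUMAN).to_numpy()]
    if len(pos) == 0 or len(neg) == 0:
        raise ConfigurationError("reference list must contain both species")
    return ref, pos, neg


def roc_points(
    outcome: TestOutcome, truth: GroundTruth, reference: Iterable[str]
) -> RocCurve:
    """ROC vertices from a test outcome against a reference list."""
    ref, pos, neg = _reference_species(truth, reference)
    p_eff = outcome.effective_p()
    present = ref.intersection(p_eff.index)
    p = p_eff.reindex(present)
    is_pos = truth.species.reindex(present).eq(ECOLI).to_numpy()
    n_pos, n_neg = len(pos), len(neg)
    order = np.argsort(p.to_numpy(), kind="stable")
    p_sorted = p.to_numpy()[order]
    pos_sorted = is_pos[order]
    # collapse ties: one vertex per distinct p-value, TP and FP advance jointly
    distinct, first_idx = np.unique(p_sorted, return_index=True)
    tp_cum = np.cumsum(pos_sorted)
    fp_cum = np.cumsum(~pos_sorted)
    last_idx = np.append(first_idx[1:], p_sorted.size) - 1
    tpr = np.concatenate([[0.0], tp_cum[last_idx] / n_pos])
    fpr = np.concatenate([[0.0], fp_cum[last_idx] / n_neg])
    thresholds = np.concatenate([[np.nan], distinct])
    return RocCurve(fpr=fpr, tpr=tpr, thresholds=thresholds)


def pauc(curve: RocCurve, fpr_max: float = 0.1) -> float:
    """Scaled partial AUC: trapezoidal area for FPR ≤ fpr_max, ceiling 100.

    TPR is linearly interpolated at the FPR boundary if no vertex falls
    there; beyond the curve's terminal vertex the TPR is extended flat
    (never-called proteins cannot be recovered at any threshold).
    """
    if not 0.0 < fpr_max <= 1.0:
        raise ConfigurationError(f"fpr_max must be in (0, 1], got {fpr_max}")
    fpr, tpr = curve.fpr, curve.tpr
    if fpr.size == 0:
        return 0.0
    if fpr[-1] < fpr_max:
        fpr = np.append(fpr, fpr_max)
        tpr = np.append(tpr, tpr[-1])
    cut = np.searchsorted(fpr, fpr_max, side="right")
    fpr_cl = fpr[:cut]
    tpr_cl = tpr[:cut]
    if fpr_cl[-1] < fpr_max:
        # interpolate the boundary point on the segment crossing fpr_max
        t_boundary = np.interp(fpr_max, fpr, tpr)
        fpr_cl = np.append(fpr_cl, fpr_max)
        tpr_cl = np.append(tpr_cl, t_boundary)
    area = np.trapezoid(tpr_cl, fpr_cl)
    return float(area * 100.0 / fpr_max)


def sensitivity_at(
    outcome: TestOutcome,
    truth: GroundTruth,
    reference: Iterable[str],
    alpha: float = 0.05,
) -> float:
    """Fraction of reference spike proteins with p < alpha (strict).

    Reference proteins absent from the outcome, or with a missing result,
    count in the denominator only.
    """
    _, pos, _ = _reference_species(truth, reference)
    p_eff = outcome.effective_p().reindex(pos)  # absent -> NaN, never significant
    return float((p_eff < alpha).sum() / len(pos))


def rmse_log2fc(
    outcome: TestOutcome, truth: GroundTruth, reference: Iterable[str]
) -> tuple[float, int]:
    """RMSE of estimated vs true log2FC over reference proteins.

    Proteins without a defined estimate are excluded; their count is
    returned alongside.  Raises if no protein has an estimate.
    """
    ref, _, _ = _reference_species(truth, reference)
    est = outcome.log2fc.reindex(ref)
    true = truth.true_log2fc.reindex(ref)
    defined = est.notna().to_numpy()
    n_excluded = int((~defined).sum())
    if not defined.any():
        raise ConfigurationError("no reference protein has a defined log2FC estimate")
    err = (est.to_numpy()[defined] - true.to_numpy()[defined]) ** 2
    return float(np.sqrt(err.mean())), n_excluded


@dataclass
class EvalResult:
    """All performance measures of one outcome against one reference list."""

    pauc: float
    sensitivity: float
    rmse: float
    n_no_estimate: int
    reference: str
    tp: int
    fp: int
    tn: int
    fn: int
    max_tpr: float


def evaluate_outcome(
    outcome: TestOutcome,
    truth: GroundTruth,
    reference: Iterable[str],
    reference_name: str = "workflow",
    fpr_max: float = 0.1,
    alpha: float = 0.05,
) -> EvalResult:
    """Score one test outcome: scaled pAUC, sensitivity, RMSE and α-counts."""
    ref, pos, neg = _reference_species(truth, reference)
    curve = roc_points(outcome, truth, reference)
    p_eff = outcome.effective_p()
    p_pos = p_eff.reindex(pos)
    p_neg = p_eff.reindex(neg)
    tp = int((p_pos < alpha).sum())
    fp = int((p_neg < alpha).sum())
    rmse, n_no_estimate = rmse_log2fc(outcome, truth, reference)
    return EvalResult(
        pauc=pauc(curve, fpr_max),
        sensitivity=sensitivity_at(outcome, truth, reference, alpha),
        rmse=rmse,
        n_no_estimate=n_no_estimate,
        reference=reference_name,
        tp=tp,
        fp=fp,
        tn=len(neg) - fp,
        fn=len(pos) - tp,
        max_tpr=curve.max_tpr,
    )


@dataclass
class MissingnessProfile:
    per_protein: pd.DataFrame  # mean_intensity, missing_fraction, species
    per_sample: pd.DataFrame  # mean_intensity, missing_fraction, condition
    correlations: dict[str, float]  # {view}_{method} -> r (NaN when undefined)


def missingness_profile(dataset: IntensityDataset) -> MissingnessProfile:
    """Per-protein and per-sample intensity/missingness table with correlations.

    Mirrors the descriptive missingness views of a spike-in acquisition:
    per-protein mean observed intensity against missing fraction, and
    per-sample mean against per-sample missingness, each with Pearson and
    Spearman correlations (NaN and flagged when a view is constant).
    """
    values = dataset.values
    per_protein = pd.DataFrame(
        {
            "mean_intensity": values.mean(axis=1, skipna=True),
            "missing_fraction": values.isna().mean(axis=1),
            "species": dataset.species,
        }
    )
    per_sample = pd.DataFrame(
        {
            "mean_intensity": values.mean(axis=0, skipna=True),
            "missing_fraction": values.isna().mean(axis=0),
            "condition": dataset.condition,
        }
    )
    correlations: dict[str, float] = {}
    for view_name, frame in (("protein", per_protein), ("sample", per_sample)):
        x = frame["mean_intensity"].to_numpy()
        y = frame["missing_fraction"].to_numpy()
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 2 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
            correlations[f"{view_name}_pearson"] = np.nan
            correlations[f"{view_name}_spearman"] = np.nan
            continue
        correlations[f"{view_name}_pearson"] = float(stats.pearsonr(x[ok], y[ok])[0])
        correlations[f"{view_name}_spearman"] = float(stats.spearmanr(x[ok], y[ok])[0])
    return MissingnessProfile(
        per_protein=per_protein, per_sample=per_sample, correlations=correlations
    )
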