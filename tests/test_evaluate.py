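import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import spikebench as sb
from spikebench.diffstats import TestOutcome as Outcome
from spikebench.synthdata import GroundTruth


def make_truth(species: dict[str, str]) -> GroundTruth:
    spec = pd.Series(species)
    fc = pd.Series({p: 1.11 if s == "ecoli" else 0.0 for p, s in species.items()})
    present = pd.Series({p: frozenset({"1:25", "1:12"}) for p in species})
    return GroundTruth(species=spec, true_log2fc=fc, present_in=present)


def make_outcome(p: dict[str, float], fc: dict[str, float] | None = None) -> Outcome:
    idx = pd.Index(p.keys())
    table = pd.DataFrame(
        {
            "p_value": pd.Series(p),
            "log2fc": pd.Series(fc) if fc else np.nan,
            "status": "tested",
        },
        index=idx,
    )
    return Outcome(table=table, method="synthetic")


def brute_force_scaled_pauc(p, labels, fpr_max=0.1):
    """Independent oracle: exhaustive threshold enumeration with plain loops.

    For every distinct p-value the (FPR, TPR) vertex is counted directly;
    consecutive vertices are joined by straight segments and the area below
    FPR = fpr_max accumulated with explicit segment clipping.
    """
    p = np.asarray(p, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    vertices = [(0.0, 0.0)]
    for threshold in sorted(set(p)):
        called = p <= threshold
        vertices.append(
            (
                float((called & ~labels).sum()) / n_neg,
                float((called & labels).sum()) / n_pos,
            )
        )
    area = 0.0
    for (x0, y0), (x1, y1) in zip(vertices[:-1], vertices[1:]):
        if x0 >= fpr_max:
            break
        if x1 <= fpr_max:
            area += (x1 - x0) * (y0 + y1) / 2.0
        else:
            # segment crosses the boundary: clip at fpr_max
            frac = (fpr_max - x0) / (x1 - x0)
            y_cut = y0 + frac * (y1 - y0)
            area += (fpr_max - x0) * (y0 + y_cut) / 2.0
            break
    else:
        # curve ends inside the window: extend flat to fpr_max
        x_end, y_end = vertices[-1]
        if x_end < fpr_max:
            area += (fpr_max - x_end) * y_end
    return float(area * 100.0 / fpr_max)


# --- reference lists -------------------------------------------------------


def test_intersection_count_floor_reproduces_14_of_17():
    sets = {f"w{i}": {"A"} for i in range(17)}
    n_workflows = 17
    min_count = int(np.floor(0.8 * n_workflows)) + 1
    assert min_count == 14
    refs = sb.build_reference_lists(sets)
    assert refs.intersection == {"A"}


def test_single_workflow_lists_coincide():
    refs = sb.build_reference_lists({"w": {"A", "B"}})
    assert refs.combined == refs.intersection == {"A", "B"}


def test_three_workflow_set_count_oracle():
    refs = sb.build_reference_lists({"w1": {"A", "B"}, "w2": {"B", "C"}, "w3": {"B"}})
    assert refs.intersection == {"B"}
    assert refs.combined == {"A", "B", "C"}


def test_empty_ensemble_rejected():
    with pytest.raises(sb.ConfigurationError):
        sb.build_reference_lists({})


# --- ROC and pAUC ----------------------------------------------------------

TRUTH4 = make_truth(
    {"E1_ECOLI": "ecoli", "E2_ECOLI": "ecoli", "H1_HUMAN": "human", "H2_HUMAN": "human"}
)


def test_perfect_separation_passes_through_origin_top():
    outcome = make_outcome({"E1_ECOLI": 0.0, "E2_ECOLI": 0.0, "H1_HUMAN": 1.0, "H2_HUMAN": 1.0})
    curve = sb.roc_points(outcome, TRUTH4, set(TRUTH4.species.index))
    assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))
    assert sb.pauc(curve) == pytest.approx(100.0)


def test_absent_spike_proteins_cap_max_tpr():
    """Spike proteins missing from the outcome are permanent false negatives."""
    outcome = make_outcome({"E1_ECOLI": 0.01, "H1_HUMAN": 0.5, "H2_HUMAN": 0.9})
    curve = sb.roc_points(outcome, TRUTH4, set(TRUTH4.species.index))
    assert curve.max_tpr == pytest.approx(0.5)


def test_tied_pvalues_advance_jointly():
    """A tied spike/human pair produces one diagonal step, not two axis steps."""
    outcome = make_outcome(
        {"E1_ECOLI": 0.01, "E2_ECOLI": 0.05, "H1_HUMAN": 0.05, "H2_HUMAN": 0.8}
    )
    curve = sb.roc_points(outcome, TRUTH4, set(TRUTH4.species.index))
    expected = [(0.0, 0.0), (0.0, 0.5), (0.5, 1.0), (1.0, 1.0)]
    assert list(zip(curve.fpr, curve.tpr)) == expected


def test_uninformative_diagonal_scores_five():
    curve = sb.RocCurve(
        fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]), thresholds=np.array([np.nan, 1.0])
    )
    assert sb.pauc(curve) == pytest.approx(5.0)


def test_pauc_validates_fpr_max():
    curve = sb.RocCurve(np.array([0.0, 1.0]), np.array([0.0, 1.0]), np.array([np.nan, 1.0]))
    with pytest.raises(sb.ConfigurationError):
        sb.pauc(curve, fpr_max=0.0)


def test_pauc_matches_brute_force_on_random_instances():
    rng = np.random.default_rng(40)
    for _ in range(30):
        n = rng.integers(10, 100)
        labels = rng.random(n) < 0.3
        if labels.all() or not labels.any():
            continue
        p = np.round(rng.random(n), 2)  # rounding creates ties
        names = [f"g{i}_{'ECOLI' if lab else 'HUMAN'}" for i, lab in enumerate(labels)]
        truth = make_truth({n_: ("ecoli" if lab else "human") for n_, lab in zip(names, labels)})
        outcome = make_outcome(dict(zip(names, p)))
        curve = sb.roc_points(outcome, truth, set(names))
        ours = sb.pauc(curve)
        ref = brute_force_scaled_pauc(p, labels)
        assert ours == pytest.approx(ref, abs=1e-10)


@given(st.floats(min_value=0.1, max_value=10.0))
@settings(max_examples=20, deadline=None)
def test_pauc_invariant_to_monotone_p_transforms(power):
    rng = np.random.default_rng(41)
    p = rng.random(50)
    labels = rng.random(50) < 0.4
    names = [f"g{i}_{'ECOLI' if lab else 'HUMAN'}" for i, lab in enumerate(labels)]
    truth = make_truth({n_: ("ecoli" if lab else "human") for n_, lab in zip(names, labels)})
    base = sb.pauc(sb.roc_points(make_outcome(dict(zip(names, p))), truth, set(names)))
    transformed = sb.pauc(
        sb.roc_points(make_outcome(dict(zip(names, p**power))), truth, set(names))
    )
    assert transformed == pytest.approx(base, abs=1e-9)


def test_p_one_negative_never_increases_pauc():
    rng = np.random.default_rng(42)
    p = rng.random(30)
    labels = np.array([True] * 10 + [False] * 20)
    names = [f"g{i}_{'ECOLI' if lab else 'HUMAN'}" for i, lab in enumerate(labels)]
    species = {n_: ("ecoli" if lab else "human") for n_, lab in zip(names, labels)}
    extra = "extra_HUMAN"
    species[extra] = "human"
    truth = make_truth(species)
    reference = set(species)
    without = make_outcome(dict(zip(names, p)))
    with_extra = make_outcome({**dict(zip(names, p)), extra: 1.0})
    assert sb.pauc(sb.roc_points(with_extra, truth, reference)) <= sb.pauc(
        sb.roc_points(without, truth, reference)
    ) + 1e-12


def test_reference_with_single_species_rejected():
    outcome = make_outcome({"H1_HUMAN": 0.5})
    with pytest.raises(sb.ConfigurationError):
        sb.roc_points(outcome, TRUTH4, {"H1_HUMAN", "H2_HUMAN"})


def test_pauc_matches_pROC_partial_auc(tmp_path):
    """Cross-check the scaled pAUC against the pROC 'auc' routine
    (partial.auc below 10% FPR, rescaled to a 100% ceiling)."""
    import subprocess

    rng = np.random.default_rng(43)
    n = 80
    labels = rng.random(n) < 0.3
    p = np.round(rng.random(n), 2)
    p[labels] *= 0.1
    names = [f"g{i}_{'ECOLI' if lab else 'HUMAN'}" for i, lab in enumerate(labels)]
    truth = make_truth({n_: ("ecoli" if lab else "human") for n_, lab in zip(names, labels)})
    ours = sb.pauc(sb.roc_points(make_outcome(dict(zip(names, p))), truth, set(names)))
    p_file, lab_file = tmp_path / "p.txt", tmp_path / "lab.txt"
    np.savetxt(p_file, p)
    np.savetxt(lab_file, labels.astype(int))
    script = (
        "suppressMessages(library(pROC))\n"
        f'p <- scan("{p_file}", quiet=TRUE); lab <- scan("{lab_file}", quiet=TRUE)\n'
        'r <- roc(lab, p, quiet=TRUE, direction=">")\n'
        'a <- auc(r, partial.auc=c(1, 0.9), partial.auc.focus="sp", partial.auc.correct=FALSE)\n'
        'cat(sprintf("%.12f", as.numeric(a) * 100 / 0.1))\n'
    )
    out = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, check=True
    )
    assert ours == pytest.approx(float(out.stdout), abs=1e-9)


# --- sensitivity and RMSE --------------------------------------------------


def test_sensitivity_counting():
    outcome = make_outcome(
        {"E1_ECOLI": 0.01, "E2_ECOLI": 0.2, "H1_HUMAN": 0.5, "H2_HUMAN": 0.9}
    )
    ref = set(TRUTH4.species.index)
    assert sb.sensitivity_at(outcome, TRUTH4, ref) == pytest.approx(0.5)
    all_sig = make_outcome({p: 0.0 for p in ref})
    assert sb.sensitivity_at(all_sig, TRUTH4, ref) == 1.0
    none_sig = make_outcome({p: 1.0 for p in ref})
    assert sb.sensitivity_at(none_sig, TRUTH4, ref) == 0.0


def test_sensitivity_absent_proteins_stay_in_denominator():
    outcome = make_outcome({"E1_ECOLI": 0.0, "H1_HUMAN": 1.0, "H2_HUMAN": 1.0})
    assert sb.sensitivity_at(outcome, TRUTH4, set(TRUTH4.species.index)) == pytest.approx(0.5)


def test_rmse_exact_cases():
    ref = set(TRUTH4.species.index)
    exact = make_outcome(
        {p: 0.5 for p in ref},
        fc={"E1_ECOLI": 1.11, "E2_ECOLI": 1.11, "H1_HUMAN": 0.0, "H2_HUMAN": 0.0},
    )
    assert sb.rmse_log2fc(exact, TRUTH4, ref)[0] == pytest.approx(0.0)

    single = make_outcome({"E1_ECOLI": 0.5}, fc={"E1_ECOLI": 0.0})
    value, excluded = sb.rmse_log2fc(single, TRUTH4, {"E1_ECOLI", "H1_HUMAN"})
    assert value == pytest.approx(1.11)
    assert excluded == 1  # H1 has no estimate

    two = make_outcome(
        {"E1_ECOLI": 0.5, "H1_HUMAN": 0.5}, fc={"E1_ECOLI": 1.5, "H1_HUMAN": 0.5}
    )
    value, _ = sb.rmse_log2fc(two, TRUTH4, {"E1_ECOLI", "H1_HUMAN"})
    assert value == pytest.approx(np.sqrt((0.25 + 0.1521) / 2))


def test_rmse_requires_an_estimate():
    empty = make_outcome({"E1_ECOLI": 0.5})
    with pytest.raises(sb.ConfigurationError):
        sb.rmse_log2fc(empty, TRUTH4, {"E1_ECOLI", "H1_HUMAN"})


def test_nested_reference_sensitivity_cap():
    """Dropping spike-only proteins from the reference can only help
    sensitivity: the removed proteins were permanent misses."""
    p = {"E1_ECOLI": 0.01, "H1_HUMAN": 0.5, "H2_HUMAN": 0.9}
    outcome = make_outcome(p)
    combined = set(TRUTH4.species.index)  # includes absent E2
    intersection = {"E1_ECOLI", "H1_HUMAN", "H2_HUMAN"}
    assert sb.sensitivity_at(outcome, TRUTH4, intersection) >= sb.sensitivity_at(
        outcome, TRUTH4, combined
    )


# --- missingness profile ---------------------------------------------------


def test_missingness_profile_counts(tiny_dataset):
    profile = sb.missingness_profile(tiny_dataset)
    assert profile.per_protein.missing_fraction.tolist() == [0.0, 0.25, 0.25]
    assert profile.per_sample.missing_fraction.tolist() == pytest.approx(
        [1 / 3, 0.0, 1 / 3, 0.0]
    )


def test_complete_matrix_correlations_flagged_undefined():
    values = pd.DataFrame(np.ones((3, 4)), index=[f"g{i}_HUMAN" for i in range(3)])
    ds = sb.IntensityDataset(
        values,
        pd.Series("human", index=values.index),
        pd.Series("1:25", index=values.columns),
    )
    profile = sb.missingness_profile(ds)
    assert all(np.isnan(v) for v in profile.correlations.values())
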