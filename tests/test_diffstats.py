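import numpy as np
import pandas as pd
import pytest
from scipy import stats

import spikebench as sb
from spikebench.diffstats import (
    STATUS_INSUFFICIENT,
    STATUS_TESTED,
    _mwu_p,
    gamma_glm_fit,
    moderated_t_pvalues,
)

from conftest import two_group_frame

PAIR = ("A", "B")
DETERMINISTIC = ("t_equal", "t_welch", "wilcoxon", "glm_gamma", "limma")


def test_estimate_log2fc_arithmetic():
    frame = pd.DataFrame(
        [[20.0, 20.0, 21.11, 21.11], [5.0, 5.0, 5.0, 5.0], [np.nan, np.nan, 3.0, 4.0]],
        index=["shift", "flat", "halfmissing"],
    )
    groups = np.array(["A", "A", "B", "B"])
    fc = sb.estimate_log2fc(frame, groups, PAIR)
    assert fc["shift"] == pytest.approx(1.11)
    assert fc["flat"] == 0.0
    assert np.isnan(fc["halfmissing"])
    out = sb.run_test(frame, groups, PAIR, "t_equal")
    assert out.status["halfmissing"] == STATUS_INSUFFICIENT
    assert out.effective_p()["halfmissing"] == 1.0


def test_t_equal_identical_groups_gives_p_one():
    frame = pd.DataFrame([[10.0, 11.0, 12.0, 10.0, 11.0, 12.0]])
    out = sb.run_test(frame, np.array(["A"] * 3 + ["B"] * 3), PAIR, "t_equal")
    assert out.p_value.iloc[0] == pytest.approx(1.0)


def test_welch_reduces_to_pooled_for_balanced_equal_variances():
    frame = pd.DataFrame([[0.0, 1.0, 2.0, 3.0, 10.0, 11.0, 12.0, 13.0]])
    groups = np.array(["A"] * 4 + ["B"] * 4)
    p_eq = sb.run_test(frame, groups, PAIR, "t_equal").p_value.iloc[0]
    p_w = sb.run_test(frame, groups, PAIR, "t_welch").p_value.iloc[0]
    assert p_eq == pytest.approx(p_w, abs=1e-12)


def test_t_tests_match_scipy_with_missing_values():
    rng = np.random.default_rng(10)
    frame, groups = two_group_frame(rng, n_genes=80, n1=7, n2=9, shift=0.4, missing=0.2)
    out_eq = sb.run_test(frame, groups, PAIR, "t_equal")
    out_w = sb.run_test(frame, groups, PAIR, "t_welch")
    a = frame.to_numpy()[:, groups == "A"]
    b = frame.to_numpy()[:, groups == "B"]
    for g in range(frame.shape[0]):
        x, y = a[g][~np.isnan(a[g])], b[g][~np.isnan(b[g])]
        if len(x) < 2 or len(y) < 2:
            assert out_eq.status.iloc[g] == STATUS_INSUFFICIENT
            continue
        assert out_eq.p_value.iloc[g] == pytest.approx(
            stats.ttest_ind(y, x).pvalue, abs=1e-12
        )
        assert out_w.p_value.iloc[g] == pytest.approx(
            stats.ttest_ind(y, x, equal_var=False).pvalue, abs=1e-12
        )


def test_wilcoxon_exact_small_sample():
    """{1,2,3} vs {4,5,6}: one-sided tail 1/20, two-sided p = 0.1."""
    assert _mwu_p(np.array([1.0, 2.0, 3.0]), np.array([4.0, 5.0, 6.0])) == pytest.approx(0.1)


def test_wilcoxon_matches_scipy_exact_and_asymptotic():
    rng = np.random.default_rng(11)
    # exact regime: small samples, continuous values
    for _ in range(25):
        x = rng.normal(size=rng.integers(2, 8))
        y = rng.normal(size=rng.integers(2, 8))
        assert _mwu_p(x, y) == pytest.approx(
            stats.mannwhitneyu(x, y, method="exact").pvalue, abs=1e-12
        )
    # asymptotic regime with ties
    for _ in range(25):
        x = rng.integers(0, 4, size=12).astype(float)
        y = rng.integers(0, 4, size=15).astype(float)
        assert _mwu_p(x, y) == pytest.approx(
            stats.mannwhitneyu(x, y, method="asymptotic").pvalue, abs=1e-10
        )


def test_gamma_glm_recovers_noiseless_log_ratio():
    a = np.array([[8.0, 9.0, 10.0, 11.0]])
    b = a + 1.11
    coef, _, _ = gamma_glm_fit(a, b)
    assert coef[0] == pytest.approx(1.11 * np.log(2.0), abs=1e-8)


def test_gamma_glm_matches_statsmodels():
    import statsmodels.api as sm

    rng = np.random.default_rng(12)
    frame, groups = two_group_frame(rng, n_genes=12, n1=8, n2=8, shift=0.5)
    out = sb.run_test(frame, groups, PAIR, "glm_gamma")
    design = sm.add_constant((np.arange(16) >= 8).astype(float))
    for g in range(12):
        y = np.exp2(frame.to_numpy()[g])
        fit = sm.GLM(y, design, family=sm.families.Gamma(sm.families.links.Log())).fit(
            scale="X2"
        )
        p_ref = 2 * stats.t.sf(abs(fit.params[1] / fit.bse[1]), 14)
        assert out.p_value.iloc[g] == pytest.approx(p_ref, abs=1e-10)


def test_degenerate_zero_variance_conventions():
    frame = pd.DataFrame(
        [[5.0, 5.0, 5.0, 5.0], [5.0, 5.0, 7.0, 7.0]], index=["flat", "sep"]
    )
    groups = np.array(["A", "A", "B", "B"])
    for method in ("t_equal", "t_welch", "glm_gamma"):
        out = sb.run_test(frame, groups, PAIR, method)
        assert out.p_value["flat"] == 1.0
        assert out.p_value["sep"] == 0.0


def test_unknown_method_raises():
    frame = pd.DataFrame([[1.0, 2.0, 3.0, 4.0]])
    with pytest.raises(sb.ConfigurationError):
        sb.run_test(frame, np.array(["A", "A", "B", "B"]), PAIR, "anova")


@pytest.mark.parametrize("method", DETERMINISTIC)
def test_label_swap_symmetry(method):
    """Swapping group labels keeps two-sided p and negates log2FC."""
    rng = np.random.default_rng(13)
    frame, groups = two_group_frame(rng, n_genes=40, n1=6, n2=6, shift=0.6, missing=0.1)
    fwd = sb.run_test(frame, groups, PAIR, method)
    rev = sb.run_test(frame, groups, ("B", "A"), method)
    ok = fwd.status == STATUS_TESTED
    assert np.allclose(
        fwd.p_value[ok].to_numpy(), rev.p_value[ok].to_numpy(), atol=1e-10
    )
    both = fwd.log2fc.notna()
    assert np.allclose(fwd.log2fc[both], -rev.log2fc[both])


def test_protein_reordering_invariance():
    rng = np.random.default_rng(14)
    frame, groups = two_group_frame(rng, n_genes=30, n1=5, n2=5, shift=0.3)
    perm = rng.permutation(frame.index)
    for method in DETERMINISTIC:
        p1 = sb.run_test(frame, groups, PAIR, method).p_value
        p2 = sb.run_test(frame.loc[perm], groups, PAIR, method).p_value
        assert np.allclose(p1.reindex(perm).to_numpy(), p2.to_numpy(), atol=1e-10)


def test_all_methods_return_valid_probabilities():
    rng = np.random.default_rng(15)
    frame, groups = two_group_frame(rng, n_genes=40, n1=5, n2=5, shift=0.5, missing=0.15)
    for method in sb.METHODS:
        p = sb.run_test(frame, groups, PAIR, method, seed=3).effective_p()
        assert ((p >= 0) & (p <= 1)).all()


# --- variance prior / moderated t -----------------------------------------


def test_equal_variances_give_infinite_prior_df():
    prior = sb.fit_variance_prior(np.full(50, 0.3), np.full(50, 8.0))
    assert np.isinf(prior.d0)
    # with d0 = inf the moderated t uses v0 in place of every s_g^2
    diff = np.array([1.0, -0.5])
    p = moderated_t_pvalues(diff, np.array([5, 5]), np.array([5, 5]), np.full(2, 0.3), np.full(2, 8.0), prior)
    z = diff / np.sqrt(prior.v0 * (1 / 5 + 1 / 5))
    assert np.allclose(p, 2 * stats.norm.sf(np.abs(z)))


def test_variance_prior_parameter_recovery():
    """Recover (d0, v0) from scaled inverse-chi-square simulated variances."""
    rng = np.random.default_rng(16)
    d0, v0, dg, n_genes = 4.0, 0.25, 8, 10_000
    sigma2 = d0 * v0 / rng.chisquare(d0, n_genes)
    s2 = sigma2 * rng.chisquare(dg, n_genes) / dg
    prior = sb.fit_variance_prior(s2, dg)
    assert abs(prior.d0 - d0) < 0.5
    assert abs(prior.v0 - v0) / v0 < 0.05


def test_variance_prior_rejects_all_zero():
    with pytest.raises(sb.ConfigurationError):
        sb.fit_variance_prior(np.zeros(10), np.full(10, 4.0))


def test_variance_prior_matches_bioconductor_limma(tmp_path):
    """Cross-check the moment fit against limma::squeezeVar via Rscript."""
    import subprocess

    rng = np.random.default_rng(17)
    s2 = 0.5 * 4 / rng.chisquare(4, 500) * rng.chisquare(8, 500) / 8
    data = tmp_path / "s2.txt"
    np.savetxt(data, s2)
    script = tmp_path / "fit.R"
    script.write_text(
        'suppressMessages(library(limma))\n'
        f's2 <- scan("{data}", quiet=TRUE)\n'
        "fit <- squeezeVar(s2, df=8)\n"
        'cat(fit$df.prior, fit$var.prior, sep="\\n")\n'
    )
    out = subprocess.run(
        ["Rscript", str(script)], capture_output=True, text=True, check=True
    )
    d0_ref, v0_ref = map(float, out.stdout.split())
    prior = sb.fit_variance_prior(s2, 8)
    assert prior.d0 == pytest.approx(d0_ref, rel=1e-4)
    assert prior.v0 == pytest.approx(v0_ref, rel=1e-4)
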