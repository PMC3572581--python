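import numpy as np
import pandas as pd
import pytest

import gancova as g
from gancova.simulate import DEFAULT_MARGINALS, _beta_params


def test_sex_counts_follow_male_fraction(pca1_truth):
    cohort = g.generate_exposures(185, 84 / 185, pca1_truth, seed=0)
    assert cohort.n_by_sex == {"male": 84, "female": 101}


def test_shared_marginal_respects_range_and_median():
    truth = g.SyntheticTruth(marginals={"age": (17, 50, 77)})
    cohort = g.generate_exposures(10_000, 0.5, truth, seed=1)
    age = cohort.data["age"]
    assert age.min() >= 17 and age.max() <= 77
    assert age.median() == pytest.approx(50, abs=1.0)


def test_per_sex_marginals_respect_their_ranges(pca1_truth):
    cohort = g.generate_exposures(4000, 84 / 185, pca1_truth, seed=2)
    for var, spec in DEFAULT_MARGINALS.items():
        for sex in ("male", "female"):
            lo, med, hi = spec[sex]
            x = cohort.data.loc[cohort.data["sex"] == sex, var]
            assert x.min() >= lo and x.max() <= hi
            assert x.median() == pytest.approx(med, rel=0.12)


def test_identity_correlation_gives_independent_draws():
    variables = ["age", "PF", "Se", "vitD"]
    marg = {v: DEFAULT_MARGINALS[v] for v in variables}
    ident = pd.DataFrame(np.eye(4), index=variables, columns=variables)
    truth = g.SyntheticTruth(marginals=marg, correlation=ident)
    cohort = g.generate_exposures(10_000, 0.5, truth, seed=3)
    sub = cohort.data[cohort.data["sex"] == "male"][variables]
    corr = sub.corr().to_numpy()
    off = corr[~np.eye(4, dtype=bool)]
    assert np.max(np.abs(off)) < 0.05


def test_infeasible_marginal_rejected():
    with pytest.raises(ValueError, match="infeasible"):
        _beta_params(10, 5, 20)
    truth = g.SyntheticTruth(marginals={"age": (17, 80, 77)})
    with pytest.raises(ValueError, match="infeasible"):
        g.generate_exposures(10, 0.5, truth, seed=0)


def test_non_psd_correlation_rejected():
    variables = ["age", "PF"]
    bad = pd.DataFrame([[1.0, 2.0], [2.0, 1.0]], index=variables,
                       columns=variables)
    with pytest.raises(ValueError, match="PSD"):
        g.SyntheticTruth(marginals={v: DEFAULT_MARGINALS[v]
                                    for v in variables}, correlation=bad)


def _noise_free(truth):
    for locus in truth.loci.values():
        locus.noise_sd = 0.0
        locus.latent_loading = 0.0
    return truth


def test_noiseless_limit_equals_linear_predictor(pca1_truth):
    truth = _noise_free(g.pca1_like_truth())
    cohort = g.generate_cohort(truth, 400, seed=4)[0]
    panel = g.generate_methylation(cohort, truth, seed=5)
    panel2 = g.generate_methylation(cohort, truth, seed=99)
    # with the noise off the draw seed is irrelevant: pure linear signal
    assert np.allclose(panel.values.to_numpy(), panel2.values.to_numpy())


def test_generating_coefficients_recovered_noise_free():
    truth = _noise_free(g.pca1_like_truth())
    cohort, panel = g.generate_cohort(truth, 10_000, seed=6)
    locus = truth.loci["PCA1like"]
    y = panel.values["PCA1like"].to_numpy()
    est = g.AncovaRegressor(locus.spec()).fit(cohort.data, y)
    # slope on raw covariates = scale * beta / covariate sd
    for name, kind in locus.spec().terms:
        sd = truth.standardization[name][1]
        expect = locus.scale * locus.betas[name] / sd
        assert est.coef_[name] == pytest.approx(expect, rel=1e-6)
    assert est.r2_ == pytest.approx(1.0, abs=1e-9)


def test_achieved_out_of_sample_ev_matches_target(pca1_truth):
    cohort, panel = g.generate_cohort(pca1_truth, 10_000, seed=7)
    locus = pca1_truth.loci["PCA1like"]
    y = panel.values["PCA1like"].to_numpy()
    est = g.AncovaRegressor(locus.spec()).fit(cohort.data, y)
    new_cohort, new_panel = g.generate_cohort(pca1_truth, 10_000, seed=8)
    y_new = new_panel.values["PCA1like"].to_numpy()
    pred = est.predict(new_cohort.data)
    ev = 1.0 - np.mean((y_new - pred) ** 2) / np.var(y_new)
    assert ev == pytest.approx(locus.target_ev, abs=0.05)


def test_wedge_noise_rises_across_age_tertiles(pca1_truth):
    cohort, panel = g.generate_cohort(pca1_truth, 2000, seed=9)
    locus = pca1_truth.loci["PCA1like"]
    y = panel.values["PCA1like"].to_numpy()
    est = g.AncovaRegressor(locus.spec()).fit(cohort.data, y)
    age = cohort.data["age"].to_numpy()
    t1, t3 = np.quantile(age, [1 / 3, 2 / 3])
    young = est.residuals_[age <= t1]
    old = est.residuals_[age >= t3]
    F = np.var(old, ddof=1) / np.var(young, ddof=1)
    from scipy import stats
    p = stats.f.sf(F, len(old) - 1, len(young) - 1)
    assert F > 1.5 and p < 1e-6


def test_null_locus_has_no_age_correlation(panel_truth):
    cohort, panel = g.generate_cohort(panel_truth, 2000, seed=10)
    from scipy import stats
    r, p = stats.pearsonr(cohort.data["age"],
                          panel.values["DKK1"].to_numpy())
    assert abs(r) < 0.08


def test_missingness_plan_gives_174_complete_cases(panel_truth):
    cohort, panel = g.generate_cohort(panel_truth, 185, seed=11)
    assert len(panel.complete_cases(["ESR1", "MYOD1", "N33"])) == 174
    assert len(panel.complete_cases(["WIF1", "SFRP1"])) == 185


def test_generation_reproducible_and_seed_sensitive(pca1_truth):
    a = g.generate_cohort(pca1_truth, 100, seed=12)
    b = g.generate_cohort(pca1_truth, 100, seed=12)
    c = g.generate_cohort(pca1_truth, 100, seed=13)
    assert a[0].data.equals(b[0].data)
    assert a[1].values.equals(b[1].values)
    assert not a[0].data.equals(c[0].data)


def test_truth_yaml_round_trip(tmp_path, pca1_truth):
    path = tmp_path / "truth.yaml"
    pca1_truth.save(path)
    loaded = g.SyntheticTruth.load(path)
    a = g.generate_cohort(pca1_truth, 50, seed=14)
    b = g.generate_cohort(loaded, 50, seed=14)
    assert a[0].data.equals(b[0].data)
    assert a[1].values.equals(b[1].values)


def test_unknown_covariate_in_truth_rejected(pca1_truth):
    truth = g.pca1_like_truth()
    truth.loci["PCA1like"].betas["nonexistent"] = 0.5
    cohort = g.generate_cohort(pca1_truth, 50, seed=15)[0]
    with pytest.raises(KeyError, match="nonexistent"):
        g.generate_methylation(cohort, truth, seed=0)
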