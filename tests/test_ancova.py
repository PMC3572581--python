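import numpy as np
import pandas as pd
import pytest
from scipy import stats

import gancova as g
from gancova.modelspec import COMMON, SEX_SPLIT, ModelSpec
from tests.conftest import random_cohort_frame

NAMES = ["age", "PF", "Se", "vitD", "MC", "BMI", "WC"]


def _random_case(rng, n=60, max_covs=3):
    frame = random_cohort_frame(rng, n=n, covariates=NAMES)
    k = rng.integers(0, max_covs + 1)
    chosen = list(rng.choice(NAMES, size=k, replace=False))
    terms = tuple(sorted(
        (c, SEX_SPLIT if rng.random() < 0.3 else COMMON) for c in chosen))
    spec = ModelSpec(terms, sex_main=bool(rng.random() < 0.5))
    y = rng.normal(size=n)
    return frame, spec, y


def _normal_equations_oracle(X, y):
    xtx_inv = np.linalg.inv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = resid @ resid / df
    se = np.sqrt(np.diag(xtx_inv) * sigma2)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    return beta, t ** 2, p


def test_fit_matches_normal_equations_oracle_on_random_instances():
    rng = np.random.default_rng(0)
    for _ in range(100):
        frame, spec, y = _random_case(rng)
        design = g.build_design(spec, frame)
        fit = g.fit_ancova(design, y)
        beta, F, p = _normal_equations_oracle(design.X, y)
        assert np.allclose(fit.coef.to_numpy(), beta, rtol=1e-8, atol=1e-12)
        table = g.ancova_table(fit, design).set_index("term")
        for j, name in enumerate(design.columns):
            if name == "intercept":
                continue
            assert table.loc[name, "F"] == pytest.approx(F[j], rel=1e-8)
            assert table.loc[name, "p"] == pytest.approx(p[j], rel=1e-6)


def test_fit_agrees_with_statsmodels():
    import statsmodels.api as sm
    rng = np.random.default_rng(1)
    frame, spec, y = _random_case(rng, n=80, max_covs=3)
    design = g.build_design(spec, frame)
    fit = g.fit_ancova(design, y)
    res = sm.OLS(y, design.X).fit()
    assert np.allclose(fit.coef.to_numpy(), res.params, rtol=1e-8)
    assert fit.r2 == pytest.approx(res.rsquared, rel=1e-8)


def test_noiseless_interpolation_and_sex_slopes():
    rng = np.random.default_rng(2)
    frame = random_cohort_frame(rng, n=40, covariates=["age"])
    codes = np.where(frame["sex"] == "male", 1.0, -1.0)
    agec = frame["age"] - frame["age"].mean()
    y = 2.0 + 3.0 * agec + 1.0 * agec * codes + 0.5 * codes
    spec = ModelSpec((("age", SEX_SPLIT),), sex_main=True)
    est = g.AncovaRegressor(spec).fit(frame, y)
    assert est.coef_["intercept"] == pytest.approx(2.0)
    assert est.coef_["age"] == pytest.approx(3.0)
    assert est.coef_["sex*age"] == pytest.approx(1.0)
    assert est.r2_ == pytest.approx(1.0)
    male, female = est.sex_slopes_["age"]
    assert male == pytest.approx(4.0) and female == pytest.approx(2.0)


def test_intercept_only_model_has_zero_r2():
    rng = np.random.default_rng(3)
    frame = random_cohort_frame(rng, n=30, covariates=["age"])
    est = g.AncovaRegressor(ModelSpec()).fit(frame, rng.normal(size=30))
    assert est.r2_ == 0.0


def test_r2_invariant_to_affine_covariate_rescaling():
    rng = np.random.default_rng(4)
    frame = random_cohort_frame(rng, n=60, covariates=["age", "PF"])
    y = rng.normal(size=60) + frame["age"].to_numpy()
    spec = ModelSpec((("PF", COMMON), ("age", SEX_SPLIT)))
    est1 = g.AncovaRegressor(spec).fit(frame, y)
    scaled = frame.copy()
    scaled["age"] = 10.0 * scaled["age"] + 100.0
    scaled["PF"] = -0.5 * scaled["PF"] + 3.0
    est2 = g.AncovaRegressor(spec).fit(scaled, y)
    assert est1.r2_ == pytest.approx(est2.r2_, rel=1e-10)
    # slopes transform consistently with the covariate scaling
    assert est2.coef_["age"] == pytest.approx(est1.coef_["age"] / 10.0)
    m1, f1 = est1.sex_slopes_["age"]
    m2, f2 = est2.sex_slopes_["age"]
    assert m2 == pytest.approx(m1 / 10.0) and f2 == pytest.approx(f1 / 10.0)


def test_duplicated_covariate_reports_rank_deficiency():
    rng = np.random.default_rng(5)
    frame = random_cohort_frame(rng, n=30, covariates=["age"])
    frame["age2"] = frame["age"]
    spec = ModelSpec((("age", COMMON), ("age2", COMMON)))
    with pytest.raises(np.linalg.LinAlgError, match="age"):
        g.AncovaRegressor(spec).fit(frame, rng.normal(size=30))


def test_too_few_observations_rejected():
    rng = np.random.default_rng(6)
    frame = random_cohort_frame(rng, n=4, covariates=NAMES)
    spec = ModelSpec(tuple((n, COMMON) for n in NAMES[:4]))
    with pytest.raises(ValueError, match="too few"):
        g.AncovaRegressor(spec).fit(frame, rng.normal(size=4))


def test_single_covariate_F_equals_squared_t_of_simple_regression():
    rng = np.random.default_rng(7)
    frame = random_cohort_frame(rng, n=50, covariates=["age"])
    y = 0.3 * frame["age"].to_numpy() + rng.normal(size=50)
    est = g.AncovaRegressor(ModelSpec((("age", COMMON),))).fit(frame, y)
    lr = stats.linregress(frame["age"], y)
    t2 = (lr.slope / lr.stderr) ** 2
    row = est.anova_table_.set_index("term").loc["age"]
    assert row["F"] == pytest.approx(t2, rel=1e-10)
    assert row["p"] == pytest.approx(lr.pvalue, rel=1e-8)


def test_terms_ordered_by_ascending_p():
    rng = np.random.default_rng(8)
    frame = random_cohort_frame(rng, n=120, covariates=["age", "PF", "Se"])
    y = 1.0 * frame["age"] + 0.3 * frame["PF"] + rng.normal(size=120)
    spec = ModelSpec((("age", COMMON), ("PF", COMMON), ("Se", COMMON)))
    est = g.AncovaRegressor(spec).fit(frame, y)
    assert np.all(np.diff(est.anova_table_["p"]) >= 0)
    assert est.ordered_terms()[0] == "age"


def test_predictions_invariant_to_training_row_order():
    rng = np.random.default_rng(9)
    frame = random_cohort_frame(rng, n=60, covariates=["age", "PF"])
    y = pd.Series(rng.normal(size=60), index=frame.index)
    spec = ModelSpec((("age", SEX_SPLIT), ("PF", COMMON)))
    est1 = g.AncovaRegressor(spec).fit(frame, y)
    perm = rng.permutation(60)
    est2 = g.AncovaRegressor(spec).fit(frame.iloc[perm], y.iloc[perm])
    assert np.allclose(est1.predict(frame), est2.predict(frame), atol=1e-10)
    # duplicated rows get duplicated predictions
    doubled = pd.concat([frame.iloc[:3]] * 2)
    pred = est1.predict(doubled)
    assert np.allclose(pred[:3], pred[3:])


def test_residuals_orthogonal_to_design():
    rng = np.random.default_rng(10)
    frame, spec, y = _random_case(rng, n=70)
    design = g.build_design(spec, frame)
    fit = g.fit_ancova(design, y)
    assert np.allclose(design.X.T @ fit.residuals, 0.0, atol=1e-8)


# ---------------------------------------------------------------------------
# wedge (heteroscedasticity) diagnostic

def test_wedge_null_calibration():
    rng = np.random.default_rng(11)
    hits = 0
    reps = 300
    for _ in range(reps):
        age = rng.uniform(17, 77, 185)
        resid = rng.normal(size=185)
        _, _, p = g.wedge_diagnostic(resid, age)
        hits += p < 0.05
    assert hits / reps == pytest.approx(0.05, abs=0.035)


def test_wedge_detects_age_proportional_noise():
    rng = np.random.default_rng(12)
    hits = 0
    reps = 60
    for _ in range(reps):
        age = rng.uniform(17, 77, 185)
        sd = 0.5 + (age - 17) / 60  # the generator's default profile shape
        resid = rng.normal(size=185) * sd
        slope, t, p = g.wedge_diagnostic(resid, age)
        hits += (p < 0.05) and (slope > 0)
    assert hits >= 0.9 * reps


def test_wedge_rejects_constant_residuals():
    with pytest.raises(ValueError, match="degenerate"):
        g.wedge_diagnostic(np.zeros(50), np.linspace(17, 77, 50))
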