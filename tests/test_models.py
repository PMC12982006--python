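"""OLS against a normal-equations oracle, VIF closed forms, standardization."""

import numpy as np
import pandas as pd
import pytest

from acsbalance import models
from acsbalance.models import (
    BASE_COVARIATES,
    CollinearityError,
    ModelSpec,
    compute_vif,
    destandardize,
    fit_linear_model,
    fit_outcome_model,
    run_analysis_suite,
    standardize_design,
)


def normal_equations(y, X):
    """Independent OLS oracle: solve X'X b = X'y directly."""
    A = np.asarray(X, dtype=float)
    return np.linalg.solve(A.T @ A, A.T @ np.asarray(y, dtype=float))


def random_design(rng, n, p):
    X = pd.DataFrame(
        rng.normal(size=(n, p)), columns=[f"x{j}" for j in range(p)]
    )
    X["const"] = 1.0
    beta = rng.normal(size=p + 1)
    y = pd.Series(X.to_numpy() @ beta + rng.normal(scale=0.5, size=n))
    return y, X


def test_ols_matches_normal_equations_oracle():
    """100 random small designs: coefficients agree to 1e-8."""
    rng = np.random.default_rng(7)
    for _ in range(100):
        n = int(rng.integers(10, 51))
        p = int(rng.integers(1, 7))
        y, X = random_design(rng, n, p)
        fit = fit_linear_model(y, X)
        oracle = normal_equations(y, X)
        got = fit.table["coef"].to_numpy()
        np.testing.assert_allclose(got, oracle[:-1], atol=1e-8, rtol=0)


def test_perfect_fit_has_zero_width_ci():
    rng = np.random.default_rng(1)
    y, X = random_design(rng, 30, 3)
    X2 = X.copy()
    y_exact = pd.Series(X2.to_numpy() @ np.array([2.0, -1.0, 0.5, 3.0]))
    fit = fit_linear_model(y_exact, X2)
    np.testing.assert_allclose(fit.table["coef"], [2.0, -1.0, 0.5], atol=1e-10)
    np.testing.assert_allclose(
        fit.table["ci_high"] - fit.table["ci_low"], 0.0, atol=1e-8
    )
    assert fit.resid_sd == pytest.approx(0.0, abs=1e-10)


def test_vif_closed_forms():
    rng = np.random.default_rng(3)
    n = 400
    # orthogonal-by-construction columns
    a = rng.normal(size=n)
    b = rng.normal(size=n)
    a = (a - a.mean()) / a.std()
    b = (b - b.mean()) / b.std()
    b = b - (a @ b / (a @ a)) * a                     # exact orthogonalization
    X = pd.DataFrame({"a": a, "b": b, "const": 1.0})
    np.testing.assert_allclose(compute_vif(X), 1.0, atol=1e-10)

    # exact sample correlation r -> VIF = 1/(1-r^2)
    r = 0.8
    c = r * a + np.sqrt(1 - r**2) * (b / b.std())
    X2 = pd.DataFrame({"a": a, "c": c, "const": 1.0})
    vifs = compute_vif(X2)
    np.testing.assert_allclose(vifs, 1.0 / (1.0 - 0.64), rtol=1e-6)

    # any design: VIF >= 1
    y, X3 = random_design(rng, 60, 5)
    assert (compute_vif(X3) >= 1.0 - 1e-12).all()


def test_rank_deficient_design_raises():
    rng = np.random.default_rng(4)
    y, X = random_design(rng, 25, 3)
    X["dup"] = 2.0 * X["x0"]
    with pytest.raises(CollinearityError):
        fit_linear_model(y, X)


def make_profiles(n=60, seed=0, beta_tpl=0.3):
    """Small synthetic profile table with a known linear TPL effect."""
    rng = np.random.default_rng(seed)
    prof = pd.DataFrame(
        {
            "facility_id": [f"F{i}" for i in range(n)],
            "is_comprehensive": rng.integers(0, 2, n),
            "in_designated_city": rng.integers(0, 2, n),
            "n_total": rng.normal(580, 300, n).clip(60),
            "n_lt34": rng.normal(32, 15, n).clip(10),
            "tpl": rng.normal(49, 16, n).clip(0, 100),
            "hdp": rng.normal(19, 8, n).clip(0, 100),
            "pprom": rng.normal(29, 11, n).clip(0, 100),
            "previa": rng.normal(5, 3, n).clip(0, 100),
            "multiple": rng.normal(11, 5, n).clip(0, 100),
            "fgr": rng.normal(14, 7, n).clip(0, 100),
            "abruption": rng.normal(6, 5, n).clip(0, 100),
            "transfer": rng.normal(50, 17, n).clip(0, 100),
            "cesarean": rng.normal(73, 11, n).clip(0, 100),
        }
    )
    prof["acs34_rate"] = (
        50.0 + beta_tpl * (prof["tpl"] - 49.0) + rng.normal(0, 8, n)
    ).clip(0, 100)
    prof["optimal34_rate"] = (0.7 * prof["acs34_rate"]).clip(0, 100)
    prof["term_acs_prop"] = rng.normal(12, 9, n).clip(0, 100)
    prof["acs_all_rate"] = rng.normal(6, 4, n).clip(0.1, 100)
    return prof


def test_standardization_closed_form_and_binaries():
    prof = make_profiles()
    spec = ModelSpec(outcome="acs34_rate")
    y, X, means, sds = standardize_design(prof, spec)
    for c in spec.covariates:
        if c in {"is_comprehensive", "in_designated_city"}:
            assert set(np.unique(X[c])) <= {0.0, 1.0}   # untouched
        else:
            assert X[c].mean() == pytest.approx(0.0, abs=1e-10)
            assert X[c].std(ddof=1) == pytest.approx(1.0, abs=1e-10)
    col = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
    z = (col["v"] - col["v"].mean()) / col["v"].std(ddof=1)
    np.testing.assert_allclose(z, [-1.0, 0.0, 1.0])


def test_zero_variance_covariate_named():
    prof = make_profiles()
    prof["hdp"] = 19.2
    with pytest.raises(ValueError, match="hdp"):
        standardize_design(prof, ModelSpec(outcome="acs34_rate"))


def test_destandardize_matches_raw_fit():
    """slope_per_SD / SD equals the slope from fitting raw columns directly."""
    prof = make_profiles(seed=5)
    std_fit = fit_outcome_model(prof, ModelSpec(outcome="acs34_rate"))
    raw_fit = fit_outcome_model(
        prof, ModelSpec(outcome="acs34_rate", standardize_continuous=False)
    )
    np.testing.assert_allclose(
        std_fit.table["raw_coef"], raw_fit.table["coef"], atol=1e-8
    )
    # identity: raw_coef * sd == standardized coef
    recon = std_fit.table["raw_coef"] * std_fit.sds.reindex(std_fit.table.index)
    np.testing.assert_allclose(recon, std_fit.table["coef"], atol=1e-10)


def test_destandardize_worked_example():
    """11.5 pp per SD with SD 16.3 pp -> 0.7055 pp per pp."""
    fit = fit_outcome_model(make_profiles(), ModelSpec(outcome="acs34_rate"))
    fit.table.loc["tpl", ["coef", "ci_low", "ci_high"]] = [11.5, 10.2, 12.8]
    sds = fit.sds.copy()
    sds["tpl"] = 16.3
    raw = destandardize(fit, sds)
    assert raw.loc["tpl", "raw_coef"] == pytest.approx(11.5 / 16.3)
    assert raw.loc["tpl", "raw_coef"] == pytest.approx(0.7055, abs=5e-4)


def test_rescaling_raw_covariate_leaves_standardized_coef_unchanged():
    prof = make_profiles(seed=8)
    fit1 = fit_outcome_model(prof, ModelSpec(outcome="acs34_rate"))
    prof2 = prof.copy()
    prof2["tpl"] = prof2["tpl"] * 10.0 + 3.0
    fit2 = fit_outcome_model(prof2, ModelSpec(outcome="acs34_rate"))
    assert fit1.table.loc["tpl", "coef"] == pytest.approx(
        fit2.table.loc["tpl", "coef"], rel=1e-10
    )


def test_suite_covariate_counts_and_outcome_exclusivity():
    prof = make_profiles()
    fits = run_analysis_suite(prof)
    assert len(fits["acs34_rate"].table) == 13
    for outcome in ("term_acs_prop", "optimal34_rate", "acs_all_rate"):
        assert len(fits[outcome].table) == 14
        assert "acs34_rate" in fits[outcome].table.index
    assert "acs34_rate" not in fits["acs34_rate"].table.index
    with pytest.raises(ValueError):
        ModelSpec(outcome="acs34_rate", covariates=BASE_COVARIATES + ["acs34_rate"])


def test_sensitivity_is_noop_without_trigger_records():
    """With abruption and Grade-1 flags cleared, sensitivity equals the main run."""
    import acsbalance as ab
    from conftest import small_config

    reg = ab.generate_registry(small_config(seed=21, n_facilities=40))
    rec = reg.records.copy()
    rec["abruption"] = 0
    rec["cesarean_grade1"] = 0

    # with no abruption anywhere its facility prevalence is constant (0), so
    # it cannot enter a standardized model; both runs drop it symmetrically
    covs = [c for c in BASE_COVARIATES if c != "abruption"]
    kw = dict(min_lt34=0, mad_k=None)
    prof, _ = ab.profiles_from_records(rec, reg.attributes, **kw)
    main = run_analysis_suite(prof, covariates=covs)
    sens = run_analysis_suite(
        prof, sensitivity=True, records=rec,
        attributes=reg.attributes, pipeline_kwargs=kw, covariates=covs,
    )
    for outcome in main:
        pd.testing.assert_frame_equal(main[outcome].table, sens[outcome].table)


def test_vifs_below_three_on_study_scale_cohort(default_cohort):
    """Collinearity gate: every VIF in all four models stays under 3."""
    fits = run_analysis_suite(default_cohort["profiles"])
    for outcome, fit in fits.items():
        assert (fit.table["vif"] < 3.0).all(), outcome
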