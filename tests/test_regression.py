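"""Net-benefit construction and OLS regression machinery."""

import numpy as np
import pandas as pd
import pytest

import nbcea as nb

from conftest import SEED, random_analysis_frame


def normal_equations(X: np.ndarray, y: np.ndarray):
    """Independent brute-force least-squares oracle with classical inference."""
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    n, k = X.shape
    sigma2 = resid @ resid / (n - k)
    cov = sigma2 * np.linalg.inv(XtX)
    return beta, np.sqrt(np.diag(cov))


@pytest.mark.parametrize(
    "effect,cost,ro,expected",
    [(1, 4000.0, 15000.0, 11000.0), (0, 1042.0, 25000.0, -1042.0),
     (1, 500.0, 0.0, -500.0), (0, 500.0, 0.0, -500.0)],
)
def test_net_benefit_formula(effect, cost, ro, expected):
    assert nb.net_benefit(effect, cost, ro) == expected


def test_net_benefit_rejects_negative_ceiling_ratio():
    with pytest.raises(nb.ConfigError):
        nb.net_benefit(1, 100.0, -1.0)


def test_intercept_only_model_recovers_the_mean():
    y = np.array([1.0, 2.0, 6.0])
    X = pd.DataFrame({"const": np.ones(3)})
    fit = nb.ols_fit(X, y)
    assert fit.params["const"] == pytest.approx(3.0)


def test_dummy_coefficient_equals_group_mean_difference():
    rng = np.random.default_rng(SEED)
    for _ in range(10):
        df = random_analysis_frame(rng)
        y = rng.normal(size=len(df))
        X = pd.DataFrame({"const": np.ones(len(df)), "sci": df["sci"].astype(float)})
        fit = nb.ols_fit(X, y)
        diff = y[df["sci"] == 1].mean() - y[df["sci"] == 0].mean()
        assert fit.params["sci"] == pytest.approx(diff, rel=1e-10, abs=1e-12)


def test_duplicated_column_raises_naming_it():
    X = pd.DataFrame({"const": np.ones(10), "a": np.arange(10.0),
                      "b": np.arange(10.0)})
    with pytest.raises(nb.ComputationError, match="b"):
        nb.ols_fit(X, np.ones(10))


def test_ols_matches_normal_equations_oracle():
    rng = np.random.default_rng(SEED + 1)
    for _ in range(25):
        df = random_analysis_frame(rng)
        nbv = nb.net_benefit(df["effect"], df["societal_cost"], 20000.0)
        X = pd.DataFrame(
            {
                "const": np.ones(len(df)),
                "edu_some": df["edu_some"].astype(float),
                "sci": df["sci"].astype(float),
            }
        )
        if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
            continue
        fit = nb.ols_fit(X, nbv)
        beta, se = normal_equations(X.to_numpy(), np.asarray(nbv, dtype=float))
        np.testing.assert_allclose(fit.params.to_numpy(), beta, rtol=1e-8)
        np.testing.assert_allclose(fit.se.to_numpy(), se, rtol=1e-8)


def test_simple_regression_on_calibrated_cohort(table1_frame):
    res = nb.simple_nb_regression(table1_frame, 0.0)
    assert round(res.delta) == -3534
    assert round(res.alpha) == -1042


def test_simple_regression_equals_arm_mean_identities(table1_frame):
    for ro in (0.0, 15000.0, 35000.0):
        res = nb.simple_nb_regression(table1_frame, ro)
        nbv = nb.net_benefit(table1_frame["effect"], table1_frame["societal_cost"], ro)
        sci = table1_frame["sci"].to_numpy()
        assert res.delta == pytest.approx(
            nbv[sci == 1].mean() - nbv[sci == 0].mean(), rel=1e-9
        )
        assert res.alpha == pytest.approx(nbv[sci == 0].mean(), rel=1e-9)


def test_delta_is_linear_in_the_ceiling_ratio(table1_frame):
    s_int = nb.group_summary(table1_frame, "intervention")
    s_comp = nb.group_summary(table1_frame, "comparison")
    de = s_int.effect_proportion - s_comp.effect_proportion
    dc = s_int.mean_cost - s_comp.mean_cost
    for res in nb.nb_regression_grid(table1_frame, nb.NBSettings((0.0, 9000.0, 28000.0, 52000.0))):
        assert res.delta == pytest.approx(de * res.ro - dc, rel=1e-9, abs=1e-9)
        assert res.alpha == pytest.approx(
            s_comp.effect_proportion * res.ro - s_comp.mean_cost, rel=1e-9, abs=1e-9
        )


def test_simple_model_f_equals_t_squared(table1_frame):
    res = nb.simple_nb_regression(table1_frame, 25000.0)
    assert res.f_stat == pytest.approx(res.t["sci"] ** 2, rel=1e-9)


def test_grid_delta_strictly_increasing_when_effect_gain_positive(table1_frame):
    deltas = [r.delta for r in
              nb.nb_regression_grid(table1_frame, nb.NBSettings(tuple(range(0, 30001, 5000))))]
    assert all(b > a for a, b in zip(deltas, deltas[1:]))


def test_empty_grid_yields_empty_results(table1_frame):
    assert nb.nb_regression_grid(table1_frame, nb.NBSettings(())) == []


def test_interactions_without_covariates_is_a_config_error():
    with pytest.raises(nb.ConfigError):
        nb.RegressionSpec(covariates=(), interactions=True)


def test_unknown_covariate_is_a_config_error():
    with pytest.raises(nb.ConfigError):
        nb.RegressionSpec(covariates=("distance_km",))


def test_identical_arms_give_zero_delta_with_p_one():
    df = random_analysis_frame(np.random.default_rng(SEED + 2), n=40)
    # mirror the intervention arm into the comparison arm
    mirrored = df.copy()
    mirrored["sci"] = 1 - mirrored["sci"]
    both = pd.concat([df, mirrored], ignore_index=True)
    res = nb.simple_nb_regression(both, 10000.0)
    assert res.delta == pytest.approx(0.0, abs=1e-9)
    assert res.delta_p == pytest.approx(1.0)


def test_adjusted_regression_recovers_null_covariates(table1_frame):
    """Covariates that do not enter the exact generator stay within noise of 0."""
    spec = nb.RegressionSpec(covariates=("edu_some", "dist_far"))
    res = nb.adjusted_nb_regression(table1_frame, 25000.0, spec)
    for term in ("edu_some", "dist_far"):
        low, high = res.conf_int(term)
        assert low < 0.0 < high


def test_rank_deficient_adjusted_design_names_offenders(table1_frame):
    df = table1_frame.copy()
    df["dist_far"] = df["edu_some"]  # force exact collinearity
    spec = nb.RegressionSpec(covariates=("edu_some", "dist_far"))
    with pytest.raises(nb.ComputationError, match="dist_far"):
        nb.adjusted_nb_regression(df, 25000.0, spec)


def test_robust_se_option_runs_and_differs(table1_frame):
    classical = nb.simple_nb_regression(table1_frame, 25000.0)
    robust = nb.simple_nb_regression(table1_frame, 25000.0, se_type="robust")
    assert robust.delta == pytest.approx(classical.delta, rel=1e-12)
    assert robust.delta_se != classical.delta_se


def test_collinearity_flags_duplicated_covariate(table1_frame):
    df = table1_frame.copy()
    df["dist_far"] = df["edu_some"]
    diag = nb.collinearity_diagnostics(df, nb.RegressionSpec(covariates=("edu_some", "dist_far")))
    assert any({a, b} == {"edu_some", "dist_far"} and abs(r) == pytest.approx(1.0)
               for a, b, r in diag.flagged_pairs)
    assert np.isinf(diag.vif["edu_some"]) or diag.vif["edu_some"] > 100


def test_independent_covariates_show_no_collinearity(table1_frame):
    diag = nb.collinearity_diagnostics(
        table1_frame, nb.RegressionSpec(covariates=("edu_some", "dist_far"))
    )
    assert abs(diag.correlations.loc["edu_some", "dist_far"]) < 0.05
    assert diag.vif["edu_some"] < 1.1


def test_asset_distance_dependence_is_flagged():
    from dataclasses import replace

    cfg = nb.get_scenario("paper_stochastic")
    cfg = replace(
        cfg,
        n_intervention=4000,
        n_comparison=4000,
        covariates=replace(cfg.covariates, asset_distance_tilt=-1.2),
    )
    records = nb.generate_cohort(cfg, seed=SEED)
    frame = nb.analysis_frame(
        nb.build_analysis_rows(records, nb.CostConfig(system_incremental_cost=3256.0))
    )
    diag = nb.collinearity_diagnostics(
        frame, nb.RegressionSpec(covariates=("dist_far", "assets")), threshold=0.15
    )
    assert any("dist_far" in (a, b) and "asset" in a + b for a, b, r in diag.flagged_pairs)


def test_grid_table_mirrors_coefficient_by_ro_layout(table1_frame):
    results = nb.nb_regression_grid(table1_frame, nb.NBSettings((0.0, 15000.0)))
    table = nb.grid_table(results)
    assert list(table.columns) == ["ro=0", "ro=15000"]
    assert table.loc["sci", "ro=0"] == pytest.approx(results[0].delta)
    assert "F" in table.index and "adj_r2" in table.index
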