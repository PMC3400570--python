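"""Acceptability curves and the CEAC-derived interval around the ICER."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

import nbcea as nb

from conftest import SEED


@pytest.mark.parametrize(
    "inb,p,expected",
    [(-100.0, 0.10, 0.05), (100.0, 0.10, 0.95), (0.0, 1.0, 0.5),
     (-1.0, 1.0, 0.5), (5.0, 0.0, 1.0)],
)
def test_p_halving_rule(inb, p, expected):
    assert nb.prob_cost_effective(inb, p) == pytest.approx(expected)


def test_p_outside_unit_interval_is_an_error():
    with pytest.raises(nb.ConfigError):
        nb.prob_cost_effective(1.0, 1.5)


def test_prob_ce_above_half_iff_positive_inb(table1_frame):
    curve = nb.ceac_curve(table1_frame, nb.NBSettings())
    for point in curve.points:
        assert (point.prob_ce >= 0.5) == (point.inb >= 0)


def test_regression_ceac_crosses_half_around_the_icer(table1_frame):
    curve = nb.ceac_curve(table1_frame, nb.NBSettings((15000.0, 35000.0)))
    assert curve.points[0].prob_ce < 0.5
    assert curve.points[1].prob_ce > 0.5


def test_curve_label_records_adjustment(table1_frame):
    spec = nb.RegressionSpec(covariates=("dist_far",))
    assert nb.ceac_curve(table1_frame, nb.NBSettings((0.0,)), spec).label == "adjusted"
    assert nb.ceac_curve(table1_frame, nb.NBSettings((0.0,))).label == "overall"


def test_identical_arms_give_a_flat_half_curve():
    rng = np.random.default_rng(SEED)
    n = 60
    half = pd.DataFrame(
        {
            "sci": 1,
            "effect": rng.integers(0, 2, size=n),
            "societal_cost": rng.gamma(2.0, 1000.0, size=n),
            "edu_some": 0, "dist_far": 0, "asset_quintile": 1,
            "asset_q2": 0, "asset_q3": 0, "asset_q4": 0, "asset_q5": 0,
        }
    )
    mirrored = half.copy()
    mirrored["sci"] = 0
    frame = pd.concat([half, mirrored], ignore_index=True)
    curve = nb.ceac_curve(frame, nb.NBSettings(tuple(range(0, 50001, 10000))))
    assert np.allclose(curve.probabilities, 0.5)


def test_analytic_ceac_published_endpoints():
    settings = nb.NBSettings((25050.0, 28500.0, 30060.0))
    curve = nb.analytic_ceac(0.124, 0.003, 3534.0, 0.0, settings)
    probs = dict(zip(curve.ro, curve.probabilities))
    assert round(probs[25050.0], 2) == 0.00
    assert round(probs[30060.0], 2) == 0.98


def test_analytic_ceac_is_half_at_the_icer():
    icer = 3534.0 / 0.124
    curve = nb.analytic_ceac(0.124, 0.003, 3534.0, 0.0, nb.NBSettings((icer,)))
    assert curve.points[0].prob_ce == pytest.approx(0.5, abs=1e-12)


def test_analytic_ceac_strictly_increasing_for_ne_tradeoff():
    curve = nb.analytic_ceac(0.124, 0.003, 3534.0, 500.0, nb.NBSettings())
    probs = curve.probabilities
    assert np.all(np.diff(probs) > 0)


def test_analytic_and_regression_curves_agree_when_increments_independent():
    """The closed-form shortcut matches the regression construction on a
    large cohort satisfying its premise (cost increment independent of the
    effect increment): household costs are zero, so the only cost is the
    constant per-household system cost and all INB variability comes from
    the effect.  With delivery-linked household costs the increments are
    positively correlated and the shortcut overstates the variance slightly.
    """
    cfg = replace(
        nb.get_scenario("paper_stochastic"),
        n_intervention=20000,
        n_comparison=20000,
        costs=nb.CostModel(hh_mean_intervention=0.0, hh_mean_comparison=0.0, cv=0.0),
    )
    records = nb.generate_cohort(cfg, seed=SEED)
    cost = nb.CostConfig(system_incremental_cost=cfg.system_incremental_cost)
    frame = nb.analysis_frame(nb.build_analysis_rows(records, cost))
    settings = nb.NBSettings(tuple(range(0, 60001, 5000)))
    reg_curve = nb.ceac_curve(frame, settings)

    s_int = nb.group_summary(frame, "intervention")
    s_comp = nb.group_summary(frame, "comparison")
    ana_curve = nb.analytic_ceac(
        s_int.effect_proportion - s_comp.effect_proportion,
        float(np.hypot(s_int.effect_se, s_comp.effect_se)),
        s_int.mean_cost - s_comp.mean_cost,
        0.0,
        settings,
    )
    np.testing.assert_allclose(
        reg_curve.probabilities, ana_curve.probabilities, atol=0.02
    )


def test_interval_brackets_the_icer():
    curve = nb.analytic_ceac(0.124, 0.003, 3534.0, 0.0, nb.NBSettings())
    ci = nb.ci_from_ceac(curve)
    icer = 3534.0 / 0.124
    assert ci.ro_low is not None and ci.ro_high is not None
    assert ci.ro_low < icer < ci.ro_high
    assert 25050.0 < ci.ro_low and ci.ro_high < 30060.0


def test_step_curve_interval_degenerates_to_the_icer():
    curve = nb.analytic_ceac(0.1, 0.0, 2000.0, 0.0, nb.NBSettings())
    ci = nb.ci_from_ceac(curve)
    assert ci.ro_low == pytest.approx(20000.0)
    assert ci.ro_high == pytest.approx(20000.0)


def test_short_grid_reports_unbounded_upper_crossing():
    curve = nb.analytic_ceac(0.124, 0.003, 3534.0, 0.0, nb.NBSettings((0.0, 27000.0)))
    ci = nb.ci_from_ceac(curve)
    assert ci.ro_high is None
    assert any("upper" in w for w in ci.warnings)


def test_stratum_curves_separate_under_a_distance_interaction():
    cfg = nb.get_scenario("distance_effect")
    cfg = replace(cfg, n_intervention=8000, n_comparison=8000)
    records = nb.generate_cohort(cfg, seed=SEED)
    cost = nb.CostConfig(system_incremental_cost=cfg.system_incremental_cost)
    frame = nb.analysis_frame(nb.build_analysis_rows(records, cost))
    settings = nb.NBSettings(tuple(range(0, 60001, 5000)))
    curves = {c.label: c for c in nb.ceac_by_stratum(frame, settings, "distance")}
    assert {"overall", "distance:near", "distance:far"} <= set(curves)
    # the far stratum has the larger effect gain here, so its curve rises first
    mid = slice(3, 9)
    assert np.mean(curves["distance:far"].probabilities[mid]) != pytest.approx(
        np.mean(curves["distance:near"].probabilities[mid]), abs=0.01
    )


def test_overall_curve_matches_simple_model_curve(table1_frame):
    settings = nb.NBSettings((0.0, 20000.0, 40000.0))
    strat = nb.ceac_by_stratum(table1_frame, settings, "distance")[0]
    simple = nb.ceac_curve(table1_frame, settings)
    np.testing.assert_allclose(strat.probabilities, simple.probabilities)


def test_single_level_stratum_warns_and_omits(table1_frame):
    frame = table1_frame.copy()
    frame["dist_far"] = 0  # everyone near
    curves = nb.ceac_by_stratum(frame, nb.NBSettings((0.0, 30000.0)), "distance")
    labels = [c.label for c in curves]
    assert "distance:far" not in labels
    assert any("distance:far" in w for w in curves[0].warnings)
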