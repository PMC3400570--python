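"""Group summaries, ICER computation and the cost-effectiveness plane."""

import math

import numpy as np
import pandas as pd
import pytest

import nbcea as nb

from conftest import SEED, random_analysis_frame


def _frame(sci, effect, cost):
    df = pd.DataFrame(
        {
            "sci": sci,
            "effect": effect,
            "societal_cost": cost,
            "edu_some": 0,
            "dist_far": 0,
            "asset_quintile": 1,
        }
    )
    for q in (2, 3, 4, 5):
        df[f"asset_q{q}"] = 0
    return df


def test_group_summary_small_example():
    df = _frame([1, 1, 1, 1], [1, 0, 0, 1], [10.0, 0.0, 0.0, 10.0])
    s = nb.group_summary(df, "intervention")
    assert s.effect_proportion == 0.5
    assert s.mean_cost == 5.0
    assert s.effect_se == pytest.approx(s.effect_sd / 2.0)


def test_calibrated_cohort_arm_summaries(table1_frame):
    comp = nb.group_summary(table1_frame, "comparison")
    assert comp.effect_proportion == pytest.approx(0.315)
    # sample SD of a Bernoulli(0.315) indicator, n-1 denominator
    assert comp.effect_sd == pytest.approx(math.sqrt(0.315 * 0.685), abs=2e-4)


def test_group_summary_matches_brute_force_on_random_cohorts():
    rng = np.random.default_rng(SEED)
    for _ in range(20):
        df = random_analysis_frame(rng)
        for arm, flag in (("intervention", 1), ("comparison", 0)):
            sub = df[df["sci"] == flag]
            s = nb.group_summary(df, arm)
            effects = sub["effect"].to_numpy(dtype=float)
            mean = effects.mean()
            sd = math.sqrt(((effects - mean) ** 2).sum() / (len(effects) - 1))
            assert s.effect_proportion == pytest.approx(mean, rel=1e-12)
            assert s.effect_sd == pytest.approx(sd, rel=1e-12)
            assert s.mean_cost == pytest.approx(sub["societal_cost"].mean(), rel=1e-12)


def _summary(n, p, cost):
    sd = math.sqrt(p * (1 - p) * n / (n - 1))
    return nb.GroupSummary(
        n=n, effect_proportion=p, effect_sd=sd, effect_se=sd / math.sqrt(n),
        mean_cost=cost,
    )


def test_icer_from_published_increments():
    res = nb.icer(_summary(40469, 0.44, 4576.0), _summary(48272, 0.316, 1042.0))
    # 3534 / 0.124 with the configured PPP rate
    assert res.icer_cfa == pytest.approx(3534.0 / 0.124, rel=1e-9)
    assert res.quadrant is nb.Quadrant.NE_TRADEOFF
    assert res.icer_cfa * res.delta_e == pytest.approx(res.delta_c, rel=1e-9)


def test_dominant_quadrant_when_cheaper_and_more_effective():
    res = nb.icer(_summary(100, 0.5, 90.0), _summary(100, 0.4, 100.0))
    assert res.quadrant is nb.Quadrant.SE_DOMINANT


def test_zero_effect_increment_flags_icer_undefined():
    res = nb.icer(_summary(100, 0.4, 200.0), _summary(100, 0.4, 100.0))
    assert not res.defined and res.icer_cfa is None
    assert "net benefit" in res.status


@pytest.mark.parametrize(
    "dc,de,quadrant",
    [
        (10.0, 0.1, nb.Quadrant.NE_TRADEOFF),
        (-10.0, 0.1, nb.Quadrant.SE_DOMINANT),
        (10.0, -0.1, nb.Quadrant.NW_DOMINATED),
        (-10.0, -0.1, nb.Quadrant.SW_TRADEOFF),
    ],
)
def test_quadrant_classification(dc, de, quadrant):
    assert nb.classify_quadrant(dc, de)[0] is quadrant


def test_zero_effect_boundary_is_labelled():
    quadrant, note = nb.classify_quadrant(10.0, 0.0)
    assert quadrant is nb.Quadrant.NE_TRADEOFF
    assert note == "no effect gain"


def test_stratified_icer_with_fixed_cost_increment():
    # education strata engineered so stratum effect increments are 0.25 and 0.07
    parts = []
    for sci, edu, n, k in [
        (1, 1, 400, 200), (0, 1, 400, 100),   # some: dE = 0.25
        (1, 0, 400, 128), (0, 0, 400, 100),   # none: dE = 0.07
    ]:
        df = _frame([sci] * n, [1] * k + [0] * (n - k), [0.0] * n)
        df["edu_some"] = edu
        parts.append(df)
    frame = pd.concat(parts, ignore_index=True)
    results = nb.stratified_icer(frame, "education", fix_delta_c=3534.0)
    by = {r.stratum: r for r in results}
    assert by["education:edu_some"].icer_cfa == pytest.approx(3534.0 / 0.25)
    assert by["education:edu_none"].icer_cfa == pytest.approx(3534.0 / 0.07)
    assert by["education:edu_some"].icer_cfa == pytest.approx(14136.0)


def test_stratified_default_fixes_overall_delta_c(table1_frame):
    results = nb.stratified_icer(table1_frame, "distance")
    overall_dc = (
        nb.group_summary(table1_frame, "intervention").mean_cost
        - nb.group_summary(table1_frame, "comparison").mean_cost
    )
    for r in results:
        if r.defined:
            assert r.delta_c == pytest.approx(overall_dc)


def test_stratum_missing_an_arm_is_flagged_not_computed():
    df = _frame([1, 1, 0, 0], [1, 0, 1, 0], [1.0, 1.0, 1.0, 1.0])
    df.loc[df["sci"] == 0, "edu_some"] = 0
    df.loc[df["sci"] == 1, "edu_some"] = 1
    results = nb.stratified_icer(df, "education", fix_delta_c=100.0)
    assert all(not r.defined for r in results)
    assert all(r.status == "stratum missing an arm" for r in results)


def test_decision_equivalence_between_icer_and_net_benefit(table1_frame):
    """sign(dE*Ro - dC) > 0 exactly when Ro exceeds the ICER (dE > 0)."""
    s_int = nb.group_summary(table1_frame, "intervention")
    s_comp = nb.group_summary(table1_frame, "comparison")
    res = nb.icer(s_int, s_comp)
    assert res.delta_e > 0
    for ro in nb.NBSettings().ro_grid:
        inb = res.delta_e * ro - res.delta_c
        assert (inb > 0) == (ro > res.icer_cfa)


def test_icer_table_layout(table1_frame):
    res = nb.stratified_icer(table1_frame, "asset")
    table = nb.icer_table(res)
    assert list(table["stratum"]) == [f"asset:q{i}" for i in range(1, 6)]
    assert {"delta_c_cfa", "icer_cfa", "icer_intl", "quadrant"} <= set(table.columns)
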