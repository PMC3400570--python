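"""Group summaries, incremental cost-effectiveness ratios and the CE plane.

The incremental cost-effectiveness ratio (ICER) is the ratio of incremental
cost to incremental effect, ICER = ΔC/ΔE, comparing the intervention arm to
the comparison arm.  Here the effect is the binary institutional-delivery
indicator, so ΔE is a difference of proportions and the ICER reads "CFA per
additional institutional delivery".  The cost-effectiveness plane classifies
(ΔE, ΔC) into dominance/trade-off quadrants.  Stratified ICERs recompute ΔE
within covariate strata while, by default, holding ΔC fixed at the overall
cost increment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import pandas as pd

from .costs import AnalysisRow, CostConfig, analysis_frame, intl_dollars_rounded
from .errors import CohortError, ConfigError

_REL_TOL = 1e-9


@dataclass(frozen=True)
class GroupSummary:
    """Per-arm sample statistics of effect and societal cost."""

    n: int
    effect_proportion: float
    effect_sd: float
    effect_se: float
    mean_cost: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise CohortError("group summary requires n >= 1")
        if not (0.0 <= self.effect_proportion <= 1.0):
            raise CohortError("effect proportion must lie in [0, 1]")


class Quadrant(str, Enum):
    """Cost-effectiveness plane quadrant for (ΔE, ΔC)."""

    NE_TRADEOFF = "NE-tradeoff"  # more effective, more costly
    SE_DOMINANT = "SE-dominant"  # more effective, less costly
    NW_DOMINATED = "NW-dominated"  # less effective, more costly
    SW_TRADEOFF = "SW-tradeoff"  # less effective, less costly


@dataclass(frozen=True)
class ICERResult:
    delta_c: float
    delta_e: float
    delta_e_se: float
    icer_cfa: float | None
    icer_intl: int | None
    quadrant: Quadrant
    defined: bool
    status: str = "ok"
    stratum: str | None = None


def group_summary(
    rows: Sequence[AnalysisRow] | pd.DataFrame, arm: str
) -> GroupSummary:
    """Summarise one arm: delivery proportion (with sample SD/SE) and mean cost.

    ``arm`` is ``"intervention"`` or ``"comparison"``.  The SD of the binary
    effect uses the n−1 denominator; its SE is SD/√n.
    """
    df = analysis_frame(rows)
    if arm not in ("intervention", "comparison"):
        raise ConfigError(f"unknown arm {arm!r}")
    sub = df[df["sci"] == int(arm == "intervention")]
    if len(sub) == 0:
        raise CohortError(f"arm {arm!r} is empty")
    n = len(sub)
    p = float(sub["effect"].mean())
    sd = float(sub["effect"].std(ddof=1)) if n > 1 else 0.0
    return GroupSummary(
        n=n,
        effect_proportion=p,
        effect_sd=sd,
        effect_se=sd / math.sqrt(n),
        mean_cost=float(sub["societal_cost"].mean()),
    )


def classify_quadrant(delta_c: float, delta_e: float) -> tuple[Quadrant, str]:
    """Classify (ΔE, ΔC) on the cost-effectiveness plane.

    Returns the quadrant and a status note.  Boundary cases are resolved
    toward the "trade-off" reading: a zero on either axis keeps the sign of
    the other axis and is labelled in the note (e.g. ΔE = 0 with ΔC > 0 sits
    on the NE boundary with note ``"no effect gain"``).
    """
    note = "ok"
    if delta_e == 0:
        note = "no effect gain" if delta_c != 0 else "no increment"
    elif delta_c == 0:
        note = "no cost increment"
    if delta_e >= 0:
        quadrant = Quadrant.NE_TRADEOFF if delta_c >= 0 else Quadrant.SE_DOMINANT
    else:
        quadrant = Quadrant.NW_DOMINATED if delta_c >= 0 else Quadrant.SW_TRADEOFF
    return quadrant, note


def icer(
    intervention: GroupSummary,
    comparison: GroupSummary,
    config: CostConfig | None = None,
    stratum: str | None = None,
    delta_c: float | None = None,
) -> ICERResult:
    """ICER from two arm summaries.

    ``delta_c`` overrides the cost increment (used by the stratified analysis
    to hold the overall ΔC fixed across strata).  A zero effect increment
    leaves the ICER undefined — the increments and quadrant are still
    reported, and the net-benefit framework should be used instead.
    """
    dc = (
        intervention.mean_cost - comparison.mean_cost
        if delta_c is None
        else float(delta_c)
    )
    de = intervention.effect_proportion - comparison.effect_proportion
    de_se = math.hypot(intervention.effect_se, comparison.effect_se)
    quadrant, note = classify_quadrant(dc, de)
    if de == 0:
        return ICERResult(
            delta_c=dc,
            delta_e=0.0,
            delta_e_se=de_se,
            icer_cfa=None,
            icer_intl=None,
            quadrant=quadrant,
            defined=False,
            status="ICER undefined (zero effect increment); use net benefit",
            stratum=stratum,
        )
    ratio = dc / de
    cfg = config or CostConfig(system_incremental_cost=0.0)
    return ICERResult(
        delta_c=dc,
        delta_e=de,
        delta_e_se=de_se,
        icer_cfa=ratio,
        icer_intl=intl_dollars_rounded(ratio, cfg),
        quadrant=quadrant,
        defined=True,
        status=note,
        stratum=stratum,
    )


# ---------------------------------------------------------------------------
# Stratified analysis
# ---------------------------------------------------------------------------

_STRATUM_LEVELS = {
    "education": ("edu_none", "edu_some"),
    "distance": ("near", "far"),
    "asset": ("q1", "q2", "q3", "q4", "q5"),
}


def _stratum_mask(df: pd.DataFrame, var: str, level: str) -> pd.Series:
    if var == "education":
        return df["edu_some"] == int(level == "edu_some")
    if var == "distance":
        return df["dist_far"] == int(level == "far")
    return df["asset_quintile"] == int(level[1])


def stratified_icer(
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    stratum_var: str,
    config: CostConfig | None = None,
    fix_delta_c: float | str | None = "overall",
) -> list[ICERResult]:
    """Per-stratum ICERs for education, distance or asset quintile strata.

    ``fix_delta_c="overall"`` (default) holds the cost increment at the
    overall value in every stratum, so only ΔE varies; pass ``None`` for
    stratum-specific ΔC, or a number to fix it explicitly.  A stratum missing
    one arm is returned flagged (``defined=False``) rather than computed.
    """
    if stratum_var not in _STRATUM_LEVELS:
        raise ConfigError(
            f"unknown stratum variable {stratum_var!r}; "
            f"expected one of {sorted(_STRATUM_LEVELS)}"
        )
    df = analysis_frame(rows)
    if fix_delta_c == "overall":
        overall = icer(
            group_summary(df, "intervention"), group_summary(df, "comparison"), config
        )
        fixed: float | None = overall.delta_c
    else:
        fixed = fix_delta_c  # None or an explicit CFA amount

    results: list[ICERResult] = []
    for level in _STRATUM_LEVELS[stratum_var]:
        sub = df[_stratum_mask(df, stratum_var, level)]
        label = f"{stratum_var}:{level}"
        try:
            s_int = group_summary(sub, "intervention")
            s_comp = group_summary(sub, "comparison")
        except CohortError:
            results.append(
                ICERResult(
                    delta_c=float("nan"),
                    delta_e=float("nan"),
                    delta_e_se=float("nan"),
                    icer_cfa=None,
                    icer_intl=None,
                    quadrant=Quadrant.NE_TRADEOFF,
                    defined=False,
                    status="stratum missing an arm",
                    stratum=label,
                )
            )
            continue
        results.append(icer(s_int, s_comp, config, stratum=label, delta_c=fixed))
    return results


def icer_table(results: Sequence[ICERResult]) -> pd.DataFrame:
    """Tabular export (one row per stratum/overall result)."""
    return pd.DataFrame(
        {
            "stratum": [r.stratum or "overall" for r in results],
            "delta_c_cfa": [r.delta_c for r in results],
            "delta_e": [r.delta_e for r in results],
            "delta_e_se": [r.delta_e_se for r in results],
            "icer_cfa": [r.icer_cfa for r in results],
            "icer_intl": [r.icer_intl for r in results],
            "quadrant": [r.quadrant.value for r in results],
            "status": [r.status for r in results],
        }
    )
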