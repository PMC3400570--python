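"""Cost-effectiveness acceptability curves and CEAC-derived ICER intervals.

A cost-effectiveness acceptability curve (CEAC) plots, against a grid of
willingness-to-pay ceiling ratios Ro, the probability that the intervention
is cost-effective.  From the net-benefit regression the probability is
obtained by halving the two-sided p-value on the treatment coefficient:
only a one-sided question is asked (is the incremental net benefit
positive?), so

    prob_ce = p/2        when the incremental net benefit is negative,
    prob_ce = 1 - p/2    when it is non-negative.

Because the incremental net benefit crosses zero exactly at Ro = ICER, the
CEAC crosses 0.5 there, and the Ro values where it crosses 2.5% and 97.5%
bracket the ICER — a confidence interval for a ratio whose direct interval
is notoriously awkward.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .costs import AnalysisRow, analysis_frame
from .errors import ConfigError
from .icer import _STRATUM_LEVELS, _stratum_mask
from .regression import (
    NBSettings,
    RegressionSpec,
    nb_regression_grid,
)

logger = logging.getLogger(__name__)


def prob_cost_effective(inb: float, p_two_sided: float) -> float:
    """Probability the intervention is cost-effective, by the p-halving rule."""
    if not (0.0 <= p_two_sided <= 1.0):
        raise ConfigError(f"two-sided p-value must lie in [0, 1], got {p_two_sided!r}")
    one_sided = p_two_sided / 2.0
    return one_sided if inb < 0 else 1.0 - one_sided


@dataclass(frozen=True)
class CEACPoint:
    ro: float
    inb: float
    se: float
    p_two_sided: float
    prob_ce: float


@dataclass
class CEACCurve:
    """Ordered CEAC points with a label (overall / stratum / adjusted tag)."""

    points: list[CEACPoint]
    label: str = "overall"
    warnings: list[str] = field(default_factory=list)

    @property
    def ro(self) -> np.ndarray:
        return np.array([p.ro for p in self.points])

    @property
    def probabilities(self) -> np.ndarray:
        return np.array([p.prob_ce for p in self.points])

    def to_frame(self, ppp_rate: float | None = None) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "ro_cfa": [p.ro for p in self.points],
                "inb": [p.inb for p in self.points],
                "se": [p.se for p in self.points],
                "p_two_sided": [p.p_two_sided for p in self.points],
                "prob_ce": [p.prob_ce for p in self.points],
            }
        )
        if ppp_rate:
            df.insert(1, "ro_intl", df["ro_cfa"] / ppp_rate)
        return df


def ceac_curve(
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    settings: NBSettings,
    spec: RegressionSpec | None = None,
    label: str | None = None,
) -> CEACCurve:
    """Regression-based CEAC: one net-benefit regression per grid point."""
    results = nb_regression_grid(rows, settings, spec)
    points = [
        CEACPoint(
            ro=r.ro,
            inb=r.delta,
            se=r.delta_se,
            p_two_sided=r.delta_p,
            prob_ce=prob_cost_effective(r.delta, r.delta_p),
        )
        for r in results
    ]
    if label is None:
        label = "adjusted" if (spec and spec.covariates) else "overall"
    return CEACCurve(points=points, label=label)


def ceac_by_stratum(
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    settings: NBSettings,
    stratum_var: str,
) -> list[CEACCurve]:
    """Overall curve plus one simple-model curve per covariate stratum.

    A stratum missing one arm is skipped with a warning attached to the
    overall curve.
    """
    if stratum_var not in _STRATUM_LEVELS:
        raise ConfigError(f"unknown stratum variable {stratum_var!r}")
    df = analysis_frame(rows)
    overall = ceac_curve(df, settings, label="overall")
    curves = [overall]
    for level in _STRATUM_LEVELS[stratum_var]:
        sub = df[_stratum_mask(df, stratum_var, level)]
        label = f"{stratum_var}:{level}"
        if sub["sci"].nunique() < 2:
            msg = f"stratum {label} missing an arm; curve omitted"
            overall.warnings.append(msg)
            logger.warning(msg)
            continue
        curves.append(ceac_curve(sub, settings, label=label))
    return curves


def analytic_ceac(
    delta_e: float,
    se_e: float,
    delta_c: float,
    se_c: float,
    settings: NBSettings,
    label: str = "analytic",
) -> CEACCurve:
    """Closed-form normal-approximation CEAC from arm-level increments.

    Treats the effect and cost increments as independent normals, so at each
    Ro the incremental net benefit dE*Ro - dC has standard error
    sqrt(Ro^2*se_e^2 + se_c^2) and prob_ce = Phi(inb/se).  With both SEs
    zero the curve degenerates to a step function at the ICER (0 below,
    1 above, 0.5 at).  Consistent with the regression-based construction on
    large cohorts with classical SEs.
    """
    points = []
    for ro in settings.ro_grid:
        inb = delta_e * ro - delta_c
        se = math.sqrt((ro * se_e) ** 2 + se_c**2)
        if se == 0:
            prob = 0.5 if inb == 0 else (1.0 if inb > 0 else 0.0)
            p_two = 1.0 if inb == 0 else 0.0
        else:
            z = inb / se
            prob = float(stats.norm.cdf(z))
            p_two = float(2 * stats.norm.sf(abs(z)))
        points.append(CEACPoint(ro=float(ro), inb=inb, se=se, p_two_sided=p_two, prob_ce=prob))
    return CEACCurve(points=points, label=label)


# ---------------------------------------------------------------------------
# Confidence interval around the ICER, read off the CEAC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CEACInterval:
    level: float
    ro_low: float | None
    ro_high: float | None
    warnings: tuple[str, ...] = ()


def _crossing(ro: np.ndarray, prob: np.ndarray, target: float) -> float | None:
    """First Ro where the curve crosses ``target``, linearly interpolated."""
    for i in range(len(ro) - 1):
        lo, hi = prob[i], prob[i + 1]
        if (lo - target) * (hi - target) <= 0 and lo != hi:
            return float(ro[i] + (target - lo) * (ro[i + 1] - ro[i]) / (hi - lo))
        if lo == target == hi:
            return float(ro[i])
    return None


def ci_from_ceac(curve: CEACCurve, level: float = 0.95) -> CEACInterval:
    """Read a confidence interval for the ICER off the acceptability curve.

    The bounds are the Ro values where prob_ce crosses (1-level)/2 and
    1-(1-level)/2, linearly interpolated between grid points.  A bound the
    grid never reaches is reported as unbounded (None) with a warning.  For
    a step-function curve (zero SEs) both crossings collapse onto the ICER.
    """
    if not (0 < level < 1):
        raise ConfigError("confidence level must lie in (0, 1)")
    ro = curve.ro
    prob = curve.probabilities
    lower_target = (1 - level) / 2
    upper_target = 1 - lower_target
    warnings: list[str] = []

    if set(np.unique(prob)) <= {0.0, 0.5, 1.0}:
        # step-function curve (zero SEs): the interval collapses onto the
        # ICER, located exactly by the zero crossing of the (linear-in-Ro) INB
        inb = np.array([p.inb for p in curve.points])
        mid = _crossing(ro, inb, 0.0)
        return CEACInterval(level=level, ro_low=mid, ro_high=mid)

    low = _crossing(ro, prob, lower_target)
    high = _crossing(ro, prob, upper_target)
    if low is None:
        warnings.append(
            f"curve never crosses {lower_target:.3f}; lower bound unbounded"
        )
        logger.warning(warnings[-1])
    if high is None:
        warnings.append(
            f"curve never crosses {upper_target:.3f}; upper bound unbounded"
        )
        logger.warning(warnings[-1])
    return CEACInterval(
        level=level, ro_low=low, ro_high=high, warnings=tuple(warnings)
    )


def curves_long_frame(
    curves: Sequence[CEACCurve], ppp_rate: float | None = None
) -> pd.DataFrame:
    """Long-format table for multi-curve plots (one row per curve x Ro)."""
    frames = []
    for c in curves:
        df = c.to_frame(ppp_rate)
        df.insert(0, "curve", c.label)
        frames.append(df)
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def plot_ceac(curves: Sequence[CEACCurve], path: str, ppp_rate: float | None = None):
    """Render CEAC curves to an image file (presentation helper)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 4.5))
    for c in curves:
        x = c.ro / ppp_rate if ppp_rate else c.ro
        ax.plot(x, c.probabilities, label=c.label)
    ax.axhline(0.5, color="grey", lw=0.5, ls="--")
    ax.set_xlabel("ceiling ratio (I$)" if ppp_rate else "ceiling ratio (CFA)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
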