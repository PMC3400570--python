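"""Net-benefit construction and OLS net-benefit regression.

For a willingness-to-pay ceiling ratio Ro (CFA per additional institutional
delivery), each household's net monetary benefit is

    NB_i = E_i * Ro - C_i

with E_i the binary effect and C_i the societal cost.  Regressing NB_i on
the treatment dummy SCI (1 = intervention district),

    NB_i = alpha + delta * SCI_i + eps_i,

gives delta = incremental net benefit: delta > 0 at a given Ro means the
incremental cost per additional delivery falls below Ro, i.e. the
intervention is cost-effective at that willingness to pay.  Algebraically
delta(Ro) = dE*Ro - dC where dE, dC are the sample increments, and
alpha(Ro) = p0*Ro - C0 from the comparison arm — the regression linearizes
the ICER and brings standard OLS inference with it.  Covariates and
treatment-by-covariate interactions extend the model to marginal
cost-effectiveness by subgroup.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .costs import AnalysisRow, analysis_frame
from .errors import ComputationError, ConfigError

#: Default willingness-to-pay grid: 0..60,000 CFA in 1,000 CFA steps.
DEFAULT_RO_GRID = tuple(range(0, 60001, 1000))

_ASSET_DUMMY_COLS = ("asset_q2", "asset_q3", "asset_q4", "asset_q5")
#: Names accepted in RegressionSpec.covariates ("assets" expands to 4 dummies).
COVARIATE_CHOICES = ("edu_some", "dist_far", "assets")


@dataclass(frozen=True)
class NBSettings:
    """Ceiling-ratio settings: a single Ro and/or a strictly increasing grid."""

    ro_grid: tuple[float, ...] = DEFAULT_RO_GRID

    def __post_init__(self) -> None:
        grid = tuple(float(r) for r in self.ro_grid)
        if any(r < 0 for r in grid):
            raise ConfigError("ceiling ratios must be >= 0")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ConfigError("ro_grid must be strictly increasing")
        object.__setattr__(self, "ro_grid", grid)

    @classmethod
    def from_range(cls, start: float, stop: float, step: float) -> "NBSettings":
        if step <= 0:
            raise ConfigError("ro grid step must be > 0")
        return cls(tuple(np.arange(start, stop + step / 2, step)))


@dataclass(frozen=True)
class RegressionSpec:
    """Which covariates enter the model, and how inference is computed.

    ``covariates`` is a subset of ``{"edu_some", "dist_far", "assets"}``
    ("assets" expands to quintile dummies, quintile 1 reference);
    ``interactions`` adds a treatment-by-covariate term for each covariate
    column; ``se_type`` selects classical (homoskedastic) or HC1 robust
    standard errors.
    """

    covariates: tuple[str, ...] = ()
    interactions: bool = False
    se_type: str = "classical"

    def __post_init__(self) -> None:
        unknown = [c for c in self.covariates if c not in COVARIATE_CHOICES]
        if unknown:
            raise ConfigError(
                f"unknown covariate(s) {unknown}; choose from {COVARIATE_CHOICES}"
            )
        if len(set(self.covariates)) != len(self.covariates):
            raise ConfigError("duplicate covariates in spec")
        if self.interactions and not self.covariates:
            raise ConfigError("interactions=True requires at least one covariate")
        if self.se_type not in ("classical", "robust"):
            raise ConfigError("se_type must be 'classical' or 'robust'")

    def covariate_columns(self) -> list[str]:
        cols: list[str] = []
        for c in self.covariates:
            cols.extend(_ASSET_DUMMY_COLS if c == "assets" else [c])
        return cols


def net_benefit(effect, cost, ro: float):
    """NB = effect*Ro - cost, elementwise (scalars or arrays)."""
    if ro < 0:
        raise ConfigError("ceiling ratio Ro must be >= 0")
    return np.asarray(effect, dtype=float) * float(ro) - np.asarray(cost, dtype=float)


# ---------------------------------------------------------------------------
# OLS core
# ---------------------------------------------------------------------------


@dataclass
class OLSFit:
    """A fitted linear model with classical or HC1 inference."""

    params: pd.Series
    se: pd.Series
    t: pd.Series
    p: pd.Series
    cov: pd.DataFrame
    f_stat: float
    f_df: tuple[int, int]
    f_pvalue: float
    adj_r2: float
    n: int
    se_type: str


def _collinear_columns(X: pd.DataFrame) -> list[str]:
    """Greedy scan naming columns that add no rank to the design."""
    bad: list[str] = []
    kept = np.empty((len(X), 0))
    rank = 0
    for col in X.columns:
        cand = np.column_stack([kept, X[col].to_numpy(dtype=float)])
        r = np.linalg.matrix_rank(cand)
        if r > rank:
            kept, rank = cand, r
        else:
            bad.append(col)
    return bad


def ols_fit(X: pd.DataFrame, y, se_type: str = "classical") -> OLSFit:
    """Ordinary least squares with full inference output.

    ``X`` must contain an intercept column and be full column rank; a
    rank-deficient design raises :class:`ComputationError` naming the
    collinear columns.  Classical covariance is s2*(X'X)^-1; ``"robust"``
    selects HC1.  Zero-residual fits are handled explicitly: a coefficient
    with zero standard error gets p = 0 when nonzero and p = 1 when zero.
    """
    y = np.asarray(y, dtype=float)
    n, k = X.shape
    if n < k:
        raise ComputationError(f"need at least {k} rows for {k} regressors, got {n}")
    if np.linalg.matrix_rank(X.to_numpy(dtype=float)) < k:
        raise ComputationError(
            "design matrix is rank deficient; collinear column(s): "
            + ", ".join(_collinear_columns(X))
        )
    model = sm.OLS(y, X)
    res = model.fit() if se_type == "classical" else model.fit(cov_type="HC1")

    se = res.bse.copy()
    t = res.tvalues.copy()
    p = res.pvalues.copy()
    degenerate = se == 0
    if degenerate.any():
        nz = degenerate & (res.params != 0)
        z = degenerate & (res.params == 0)
        t[nz] = np.inf * np.sign(res.params[nz])
        p[nz] = 0.0
        t[z] = 0.0
        p[z] = 1.0
    return OLSFit(
        params=res.params,
        se=se,
        t=t,
        p=p,
        cov=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        f_stat=float(res.fvalue) if res.fvalue is not None else float("nan"),
        f_df=(int(res.df_model), int(res.df_resid)),
        f_pvalue=float(res.f_pvalue) if res.f_pvalue is not None else float("nan"),
        adj_r2=float(res.rsquared_adj),
        n=n,
        se_type=se_type,
    )


# ---------------------------------------------------------------------------
# Net-benefit regressions
# ---------------------------------------------------------------------------


@dataclass
class RegressionResult:
    """One net-benefit regression at one ceiling ratio.

    ``alpha`` is the constant, ``delta`` the treatment (SCI) coefficient —
    the incremental net benefit — ``betas`` covariate main effects and
    ``gammas`` treatment-by-covariate interaction coefficients, all in CFA.
    ``se``/``t``/``p`` are keyed by term name (``"const"``, ``"sci"``,
    covariate and ``"sci:<covariate>"`` names).
    """

    ro: float
    alpha: float
    delta: float
    betas: dict[str, float]
    gammas: dict[str, float]
    se: dict[str, float]
    t: dict[str, float]
    p_two_sided: dict[str, float]
    f_stat: float
    f_df: tuple[int, int]
    f_pvalue: float
    adj_r2: float
    n: int
    se_type: str = "classical"
    label: str = "simple"

    @property
    def delta_se(self) -> float:
        return self.se["sci"]

    @property
    def delta_p(self) -> float:
        return self.p_two_sided["sci"]

    def conf_int(self, term: str = "sci", level: float = 0.95) -> tuple[float, float]:
        """Two-sided t-based confidence interval for a coefficient."""
        from scipy import stats

        coef = {"const": self.alpha, "sci": self.delta, **self.betas, **self.gammas}[term]
        half = stats.t.ppf(0.5 + level / 2, self.f_df[1]) * self.se[term]
        return coef - half, coef + half


def _design(df: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    cols = {"const": np.ones(len(df))}
    for c in spec.covariate_columns():
        cols[c] = df[c].to_numpy(dtype=float)
    cols["sci"] = df["sci"].to_numpy(dtype=float)
    if spec.interactions:
        for c in spec.covariate_columns():
            cols[f"sci:{c}"] = cols["sci"] * cols[c]
    return pd.DataFrame(cols, index=df.index)


def _fit_to_result(
    fit: OLSFit, ro: float, spec: RegressionSpec, label: str
) -> RegressionResult:
    betas = {
        c: float(fit.params[c]) for c in fit.params.index if c not in ("const", "sci")
        and not c.startswith("sci:")
    }
    gammas = {
        c: float(fit.params[c]) for c in fit.params.index if c.startswith("sci:")
    }
    return RegressionResult(
        ro=ro,
        alpha=float(fit.params["const"]),
        delta=float(fit.params["sci"]),
        betas=betas,
        gammas=gammas,
        se={c: float(fit.se[c]) for c in fit.params.index},
        t={c: float(fit.t[c]) for c in fit.params.index},
        p_two_sided={c: float(fit.p[c]) for c in fit.params.index},
        f_stat=fit.f_stat,
        f_df=fit.f_df,
        f_pvalue=fit.f_pvalue,
        adj_r2=fit.adj_r2,
        n=fit.n,
        se_type=fit.se_type,
        label=label,
    )


def simple_nb_regression(
    rows: Sequence[AnalysisRow] | pd.DataFrame, ro: float, se_type: str = "classical"
) -> RegressionResult:
    """NB_i = alpha + delta*SCI_i + eps_i at one ceiling ratio.

    ``delta`` equals the difference in mean net benefit between arms and
    ``alpha`` the comparison-arm mean net benefit (exact OLS identities for
    a single-dummy design); p-values come from the t distribution with n-2
    residual degrees of freedom.
    """
    df = analysis_frame(rows)
    if df["sci"].nunique() < 2:
        raise ComputationError("both arms required for the net-benefit regression")
    spec = RegressionSpec()
    nb = net_benefit(df["effect"], df["societal_cost"], ro)
    fit = ols_fit(_design(df, spec), nb, se_type=se_type)
    return _fit_to_result(fit, float(ro), spec, label="simple")


def adjusted_nb_regression(
    rows: Sequence[AnalysisRow] | pd.DataFrame, ro: float, spec: RegressionSpec
) -> RegressionResult:
    """Covariate-adjusted (and optionally interaction) net-benefit regression.

    Interaction coefficients (treatment-by-covariate) measure how the
    incremental net benefit — hence cost-effectiveness — varies at the
    margin across subgroups.
    """
    if not spec.covariates:
        raise ConfigError("adjusted regression requires at least one covariate")
    df = analysis_frame(rows)
    if df["sci"].nunique() < 2:
        raise ComputationError("both arms required for the net-benefit regression")
    nb = net_benefit(df["effect"], df["societal_cost"], ro)
    fit = ols_fit(_design(df, spec), nb, se_type=spec.se_type)
    label = "adjusted+interactions" if spec.interactions else "adjusted"
    return _fit_to_result(fit, float(ro), spec, label=label)


def nb_regression_grid(
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    settings: NBSettings,
    spec: RegressionSpec | None = None,
) -> list[RegressionResult]:
    """One net-benefit regression per ceiling ratio on the grid, in order."""
    df = analysis_frame(rows)
    out: list[RegressionResult] = []
    for ro in settings.ro_grid:
        if spec is None or not spec.covariates:
            out.append(simple_nb_regression(df, ro, (spec or RegressionSpec()).se_type))
        else:
            out.append(adjusted_nb_regression(df, ro, spec))
    return out


def grid_table(results: Sequence[RegressionResult]) -> pd.DataFrame:
    """Coefficient-by-ceiling-ratio matrix (coefficients as rows, Ro as columns).

    Mirrors the familiar published layout: constant and treatment rows with
    bracketed SEs and p-values flattened into separate rows, then overall F
    and adjusted R2.
    """
    if not results:
        return pd.DataFrame()
    terms = ["const", "sci"] + [
        c for c in results[0].se if c not in ("const", "sci")
    ]
    data: dict[str, list[float]] = {}
    for res in results:
        coef = {"const": res.alpha, "sci": res.delta, **res.betas, **res.gammas}
        col: list[float] = []
        for term in terms:
            col.extend([coef[term], res.se[term], res.p_two_sided[term]])
        col.extend([res.f_stat, res.adj_r2])
        data[f"ro={res.ro:g}"] = col
    index = [
        f"{term}{suffix}" for term in terms for suffix in ("", " [se]", " (p)")
    ] + ["F", "adj_r2"]
    return pd.DataFrame(data, index=index)


# ---------------------------------------------------------------------------
# Collinearity diagnostics
# ---------------------------------------------------------------------------


@dataclass
class CollinearityDiagnostics:
    correlations: pd.DataFrame
    vif: pd.Series
    flagged_pairs: list[tuple[str, str, float]]
    constant_columns: list[str] = field(default_factory=list)


def collinearity_diagnostics(
    rows: Sequence[AnalysisRow] | pd.DataFrame,
    spec: RegressionSpec,
    threshold: float = 0.7,
) -> CollinearityDiagnostics:
    """Pairwise correlations and variance inflation factors for the design.

    Computed over the non-intercept columns (covariates, treatment and any
    interactions).  Pairs with |r| above ``threshold`` are flagged; a
    zero-variance column has undefined VIF and is flagged separately.
    Observed interactions in the adjusted model can be artefacts of such
    collinearity, so these diagnostics guide which covariates to keep.
    """
    df = analysis_frame(rows)
    X = _design(df, spec).drop(columns="const")
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    corr = X.corr()
    flagged = []
    cols = list(X.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            r = corr.loc[a, b]
            if np.isfinite(r) and abs(r) >= threshold:
                flagged.append((a, b, float(r)))
    vif = {}
    for c in cols:
        if c in constant:
            vif[c] = float("nan")
            continue
        others = [o for o in cols if o != c and o not in constant]
        Z = pd.DataFrame({"const": np.ones(len(X))})
        for o in others:
            Z[o] = X[o].to_numpy(dtype=float)
        resid = sm.OLS(X[c].to_numpy(dtype=float), Z).fit()
        r2 = resid.rsquared
        vif[c] = float("inf") if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return CollinearityDiagnostics(
        correlations=corr,
        vif=pd.Series(vif),
        flagged_pairs=flagged,
        constant_columns=constant,
    )
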