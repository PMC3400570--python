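# Methods

## Model and procedure

The package analyses a two-arm observational design: an intervention
district and a comparison district, one record per surveyed household with
a recent delivery.  The effect E is binary (institutional delivery) and the
cost C is societal: household out-of-pocket spending plus the health
system's incremental cost of the intervention package.  Attribution rules:

| arm | delivered | societal cost |
| --- | --- | --- |
| intervention | yes | household cost + system incremental cost |
| intervention | no | system incremental cost |
| comparison | yes | household cost |
| comparison | no | 0 |

The comparison arm carries no system cost because the standard provision of
maternal care is assumed identical in both districts: it cancels out of
every incremental quantity, leaving only the intervention package's extra
system cost.  The system incremental cost is an input parameter (it comes
from a separate facility costing exercise, not from this analysis).  An
alternative attribution that charges the system cost only to delivering
households exists behind `CostConfig.per_delivery_only` and is off by
default.

Given attributed rows, the analysis proceeds as: arm summaries → ICER
(ΔC/ΔE) with plane quadrant → net-benefit regression
NB\_i = E\_i·R₀ − C\_i on the treatment dummy over a ceiling-ratio grid →
CEAC by the p-halving rule → confidence interval for the ICER from the
curve's 2.5%/97.5% crossings.  The identities

- δ̂(R₀) = ΔÊ·R₀ − ΔĈ and α̂(R₀) = p̂₀·R₀ − Ĉ₀ (exact OLS algebra for a
  single dummy regressor),
- δ̂ > 0 ⟺ R₀ > ICER (for ΔÊ > 0),
- F = t² for the single-regressor model,

are asserted in the test suite at 10⁻⁹ relative tolerance.

## Treatment coding

SCI = 1 for intervention-district households.  This is the coding under
which the published-style signs come out (incremental net benefit −3,534
CFA at R₀ = 0 with constant −1,042 CFA, i.e. minus the cost increment and
minus the comparison-arm mean cost) and under which "δ > 0 means the
intervention is cost-effective" reads correctly.

## Parameters that matter

- **system_incremental_cost** (CFA per intervention-district household;
  calibration value 3,256): the health-system cost of the intervention
  package, attributed to every intervention-arm household.
- **ppp_rate** (CFA per international dollar, default 167): used only at
  the reporting boundary; all arithmetic stays in CFA, and I$ figures are
  integer-rounded half away from zero.
- **distance threshold** (default 5 km): households strictly beyond it are
  "far".  The boundary itself is assigned to the near stratum — a household
  at exactly 5 km counts as near — and this choice is deliberate and fixed.
- **R₀ grid** (default 0–60,000 CFA in 1,000 CFA steps): covers the region
  around the ICER (≈28,000 CFA) with room on both sides; CEAC confidence
  intervals interpolate linearly between grid points, so a finer grid
  tightens the bracket.
- **se_type**: classical (homoskedastic) OLS standard errors by default,
  matching the plain-OLS construction; HC1 robust errors by flag.  P-values
  use the t distribution with n − k degrees of freedom.  No multiple-testing
  correction is applied across the R₀ grid: the grid profiles one statistic,
  it is not a family of hypotheses.

## Synthetic cohorts

The generator emulates the study conditions rather than any deposited data
(none exist).  Defaults were fixed once, on the following reasoning:

- **Delivery**: logistic in the arm indicator and covariates — the minimal
  covariate-dependent Bernoulli model.  Scenario `paper_stochastic` uses
  log-odds −0.5 for the >5 km flag, +0.4 for some education, +0.1 per asset
  quintile step (directions and rough magnitudes any determinants study
  would recognise), with the intercept and arm effect solved by root
  finding over the exact discrete covariate law so the marginal delivery
  proportions are exactly 31.5% and 44% at the study's arm sizes
  (48,272 / 40,469).
- **Distance**: Gamma(shape 2, scale 3) km — mean 6 km, right-skewed, both
  sides of the 5 km threshold well populated (P(far) ≈ 0.5).
- **Costs**: household delivery costs Gamma-distributed with arm means
  3,000 / 3,308 CFA and CV 0.5 (non-negative and right-skewed, as
  out-of-pocket spending is); no dispersion is published, so the CV is a
  stated assumption.
- **Education / assets**: P(some education) = 0.3; asset quintiles uniform,
  optionally tilted within the far stratum (`asset_distance_tilt`) to
  induce the distance–wealth collinearity seen in field data.
- **Exact mode** (`table1_exact`): 10,000 households per arm; delivery
  counts are round(n·p) assigned by a seeded permutation and every
  delivering household receives the arm's fixed household cost, so the arm
  proportions (44% / 31.5%) and attributed cost means (4,576 / 1,042.02
  CFA) hold exactly.  The implied cost increment is 3,533.98 CFA and effect
  increment 0.125, hence an ICER of 28,272 CFA — a calibration cohort, not
  a reconstruction of the original survey, whose unrounded increments gave
  a slightly different printed ratio.
- **`null`**: identical arms (no arm effect, equal cost models, zero system
  cost), 2,000 households per arm — used for type-I error calibration.
- **`distance_effect`**: +0.6 log-odds treatment-by-distance interaction.
  Its implied coefficient on the net-benefit scale at a given R₀ is
  computed in closed form (`expected_nb_interaction`) from the four
  (arm × distance) cell probabilities and the cost means, and used as the
  truth in coverage tests.

Determinism: one integer master seed; each arm draws from its own
`SeedSequence` substream, so resizing one arm leaves the other unchanged.

What the generator does **not** emulate: village-level clustering (and so
no clustered standard errors), spatial facility placement, fertility and
mortality processes, measurement error in distance or assets, and any
correlation between household cost and covariates.  Tests passing on these
cohorts show the machinery is correct under the stated model, not that the
model captures every feature of real survey data.

## Numerical choices

- OLS is fitted by statsmodels; an independent normal-equations solve is
  used as a test oracle.  Rank-deficient designs raise an error naming the
  collinear columns (greedy rank scan).
- Zero-residual (degenerate) fits: a coefficient with zero standard error
  gets p = 0 when nonzero and p = 1 when zero, so identical arms yield a
  flat CEAC at 0.5 rather than NaNs.
- ΔE = 0 leaves the ICER undefined with an explanatory status (not ±∞);
  plane-quadrant boundaries keep the sign of the non-zero axis and carry a
  note (e.g. "no effect gain").
- CEAC interval crossings are linearly interpolated; for a zero-SE step
  curve the interval collapses onto the ICER, located exactly via the
  linear-in-R₀ INB.
- The closed-form CEAC treats the effect and cost increments as independent
  normals (SE\_C defaults to 0 when cost variability is not supplied).
  **Limitation**: with delivery-linked household costs the increments are
  positively correlated — cov(E, C) ≈ hh\_mean·var(E) — so the shortcut
  overstates the INB variance and can differ from the regression-based
  curve by up to a few percent probability near the ICER, independent of
  sample size.  The two constructions agree within 0.02 when the
  independence premise holds (e.g. cost variation not tied to delivery);
  the regression-based curve is the primary object.
- Missing delivery costs: strict mode errors naming the row; lenient mode
  imputes the arm-specific mean of observed delivery costs with a logged
  warning.

## Problem sizes

The deterministic calibration cohort uses 10,000 households per arm (large
enough that integer delivery counts represent the target proportions
exactly and regressions are instant).  Monte-Carlo calibration (type-I
rate, interaction CI coverage) uses 500 replicates of 2,000 households per
arm — the rate then carries a Monte-Carlo SE of about 1 percentage point,
which the ±2-point acceptance bands reflect.  Stochastic moment checks use
single cohorts of 50,000 per arm (3-SD binomial/Gamma bands).

## Known limitations

- Covariate-adjusted results published at the original survey scale (e.g.
  an adjusted R² around 13%, subgroup probabilities at R₀ = 60,000 CFA)
  depend on unpublished inputs and are treated as qualitative context, not
  reproduction targets.
- The wealth index is consumed as a given quintile (or ranked from a raw
  score); principal-component construction of asset indices is out of
  scope, as are mortality outcomes and geo-referencing.
- Standard errors assume independent households; with village-level
  intervention delivery, true design effects would widen them.
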