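# nbcea — net-benefit cost-effectiveness analysis for household survey data

`nbcea` implements the net-benefit framework for two-arm observational
cost-effectiveness studies in which *household-level* effect and cost data
are available — the setting of maternal and newborn health evaluations
where one district receives an intervention package and a comparison
district keeps the standard of care, the effect is a binary institutional
delivery indicator, and costs combine household out-of-pocket spending with
the health system's incremental cost (a societal perspective).

## The statistics

The traditional summary is the incremental cost-effectiveness ratio

> ICER = ΔC / ΔE,

the extra cost per additional institutional delivery.  Confidence intervals
for this ratio are notoriously awkward, and stratified ICERs cannot be
adjusted jointly for covariates.  The net-benefit framework linearizes the
problem: for a willingness-to-pay ceiling ratio *R₀*, each household *i*
gets a net monetary benefit

> NB\_i = E\_i·R₀ − C\_i,

and the OLS regression

> NB\_i = α + δ·SCI\_i + Σ\_j β\_j x\_ij (+ Σ\_j γ\_j SCI\_i·x\_ij) + ε\_i

is run over a grid of R₀ values (SCI is the treatment dummy, 1 in the
intervention district).  The treatment coefficient δ is the **incremental
net benefit**: δ > 0 at a given R₀ exactly when R₀ exceeds the ICER, and
standard OLS inference applies.  Halving the two-sided p-value on δ gives
the probability that the intervention is cost-effective (p/2 for δ < 0,
1 − p/2 otherwise); plotted against R₀ this is the **cost-effectiveness
acceptability curve (CEAC)**, and the R₀ values where the curve crosses
2.5% and 97.5% form a 95% confidence interval around the ICER.  Interaction
terms γ\_j show how cost-effectiveness varies at the margin by subgroup
(education, distance to facility, asset quintile).

## What is in the package

- `records` — household CSV schema, strict/lenient validation, covariate
  derivation (education none/some, >5 km distance flag, asset dummies).
- `costs` — societal cost attribution (household cost + system incremental
  cost by arm and delivery status), PPP conversion to international dollars.
- `icer` — group summaries, overall and stratified ICERs,
  cost-effectiveness-plane quadrants.
- `regression` — net-benefit construction, simple / covariate-adjusted /
  interaction OLS models over a ceiling-ratio grid, collinearity
  diagnostics (correlations, VIFs).
- `ceac` — regression-based and closed-form acceptability curves,
  per-stratum curves, CEAC-derived confidence intervals.
- `simulate` — synthetic two-district cohort generator with calibrated
  (exact) and stochastic modes plus a scenario library.
- `pipeline` / `cli` — end-to-end runs with a manifest, and a thin
  command-line interface (`nbcea report --scenario table1_exact --out run/`).

## Worked example

```python
import nbcea as nb

cfg = nb.get_scenario("table1_exact")          # calibrated 10,000/arm cohort
records = nb.generate_cohort(cfg, seed=1)
cost = nb.CostConfig(system_incremental_cost=cfg.system_incremental_cost)
frame = nb.analysis_frame(nb.build_analysis_rows(records, cost))

res = nb.icer(nb.group_summary(frame, "intervention"),
              nb.group_summary(frame, "comparison"), cost)
print(res.delta_c, res.delta_e, round(res.icer_cfa), res.icer_intl)
# 3533.98 0.125 28272 169

grid = nb.nb_regression_grid(frame, nb.NBSettings((0.0, 25000.0, 35000.0)))
print([round(r.delta) for r in grid])
# [-3534, -409, 841]
```

The cohort is calibrated so that delivery proportions are 44% vs 31.5% and
arm mean societal costs 4,576 vs 1,042 CFA; the cost increment is 3,534 CFA
and the effect increment 0.125, giving an ICER of 28,272 CFA ≈ I$169 per
additional institutional delivery (167 CFA per international dollar).  At
R₀ = 0 the incremental net benefit is minus the cost increment (−3,534 CFA);
it turns positive between 25,000 and 35,000 CFA — the intervention becomes
cost-effective once a payer values an extra institutional delivery above
the ICER.  The scripts in `examples/` walk through the ICER table, the
regression grid, the CEAC with its confidence interval, and subgroup
interaction analysis, each printing the numbers it computes.

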