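"""End-to-end orchestration: data in, full result bundle out.

A run executes read/generate -> validate -> cost attribution -> ICER
(overall and stratified) -> net-benefit regression grid (simple, plus
adjusted/interaction models and collinearity diagnostics when covariates
are requested) -> CEACs (overall, adjusted, per-stratum) -> CEAC-derived
confidence interval, and writes every export table plus a machine-readable
manifest.  The run is a pure function of (input data, config, seed).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from . import __version__
from .ceac import ceac_by_stratum, ceac_curve, ci_from_ceac, curves_long_frame
from .costs import CostConfig, analysis_frame, build_analysis_rows
from .errors import ConfigError, NBCEAError
from .icer import group_summary, icer, icer_table, stratified_icer
from .records import read_household_table, validate_cohort, write_household_table
from .regression import (
    NBSettings,
    RegressionSpec,
    collinearity_diagnostics,
    grid_table,
    nb_regression_grid,
)
from .simulate import generate_cohort, get_scenario

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on."""

    output_dir: str
    input_path: str | None = None
    scenario: str | None = None
    cost: CostConfig | None = None
    settings: NBSettings = field(default_factory=NBSettings)
    spec: RegressionSpec = field(default_factory=RegressionSpec)
    strata: tuple[str, ...] = ("education", "distance", "asset")
    ceac_stratum: str = "distance"
    seed: int = 0
    strict: bool = True
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if (self.input_path is None) == (self.scenario is None):
            raise ConfigError("supply exactly one of input_path or scenario")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "RunConfig":
        m = dict(mapping)
        cost = CostConfig.from_mapping(m) if "cost" in m else None
        reg = m.get("regression", {})
        spec = RegressionSpec(
            covariates=tuple(reg.get("covariates", ())),
            interactions=bool(reg.get("interactions", False)),
            se_type=reg.get("se_type", "classical"),
        )
        grid = m.get("ro_grid")
        settings = (
            NBSettings.from_range(grid["start"], grid["stop"], grid["step"])
            if grid
            else NBSettings()
        )
        return cls(
            output_dir=m["output_dir"],
            input_path=m.get("input_path"),
            scenario=m.get("scenario"),
            cost=cost,
            settings=settings,
            spec=spec,
            strata=tuple(m.get("strata", ("education", "distance", "asset"))),
            ceac_stratum=m.get("ceac_stratum", "distance"),
            seed=int(m.get("seed", 0)),
            strict=bool(m.get("strict", True)),
            log_level=m.get("log_level", "INFO"),
        )

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh) or {})


@dataclass
class RunBundle:
    """Paths and key estimates produced by one run."""

    output_dir: Path
    outputs: dict[str, str]
    manifest: dict[str, Any]


def _write_json(path: Path, payload: Any) -> None:
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")


def run_pipeline(config: RunConfig) -> RunBundle:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    probe = outdir / ".write_probe"
    try:
        probe.write_text("")
        probe.unlink()
    except OSError as exc:  # abort before any computation
        raise ConfigError(f"output directory not writable: {exc}") from exc

    outputs: dict[str, str] = {}
    warnings: list[str] = []

    def register(name: str, path: Path) -> Path:
        outputs[name] = str(path)
        return path

    # --- stage 1: load or generate -----------------------------------------
    if config.scenario is not None:
        gen = get_scenario(config.scenario)
        records = generate_cohort(gen, seed=config.seed)
        logger.info("generated scenario %r: %d records", config.scenario, len(records))
        write_household_table(records, str(register("cohort", outdir / "cohort.csv")))
        cost = config.cost or CostConfig(
            system_incremental_cost=gen.system_incremental_cost
        )
    else:
        records, report = read_household_table(config.input_path, strict=config.strict)
        logger.info(
            "read %d records from %s (%d dropped, %d imputed)",
            report.n_parsed, config.input_path, report.n_dropped, report.n_imputed_costs,
        )
        warnings.extend(report.warnings + report.row_errors)
        if config.cost is None:
            raise ConfigError(
                "a cost configuration (system_incremental_cost, ppp_rate) is "
                "required when analysing a cohort file"
            )
        cost = config.cost

    # --- stage 2: validation ------------------------------------------------
    validation = validate_cohort(records)
    logger.info("cohort valid: %s", validation)
    _write_json(
        register("validation", outdir / "validation.json"),
        {
            "n_records": validation.n_records,
            "arms": {k: dataclasses.asdict(v) for k, v in validation.arms.items()},
            "missingness": validation.missingness,
        },
    )

    # --- stage 3: cost attribution -----------------------------------------
    rows = build_analysis_rows(records, cost)
    frame = analysis_frame(rows)

    # --- stage 4: summaries and ICER ---------------------------------------
    s_int = group_summary(frame, "intervention")
    s_comp = group_summary(frame, "comparison")
    overall = icer(s_int, s_comp, cost)
    logger.info(
        "increments: dC=%.1f CFA, dE=%.4f; ICER=%s",
        overall.delta_c, overall.delta_e,
        f"{overall.icer_cfa:.0f} CFA (I${overall.icer_intl})" if overall.defined
        else "undefined",
    )
    strat_results = []
    for var in config.strata:
        strat_results.extend(stratified_icer(frame, var, cost))
    icer_table([overall] + strat_results).to_csv(
        register("icer", outdir / "icer.csv"), index=False
    )
    _write_json(
        register("icer_json", outdir / "icer.json"),
        {
            "intervention": dataclasses.asdict(s_int),
            "comparison": dataclasses.asdict(s_comp),
            "overall": {
                **{k: v for k, v in dataclasses.asdict(overall).items()
                   if k != "quadrant"},
                "quadrant": overall.quadrant.value,
            },
        },
    )

    # --- stage 5: regression grid ------------------------------------------
    simple_grid = nb_regression_grid(frame, config.settings)
    grid_table(simple_grid).to_csv(register("regression_grid", outdir / "regression_grid.csv"))
    logger.info(
        "simple NB regression: delta at Ro=%g is %.1f CFA",
        simple_grid[0].ro, simple_grid[0].delta,
    )

    adjusted_grid = None
    if config.spec.covariates:
        adjusted_grid = nb_regression_grid(frame, config.settings, config.spec)
        grid_table(adjusted_grid).to_csv(
            register("adjusted_grid", outdir / "adjusted_grid.csv")
        )
        diag = collinearity_diagnostics(frame, config.spec)
        diag.correlations.to_csv(register("collinearity", outdir / "collinearity.csv"))
        _write_json(
            register("vif", outdir / "vif.json"),
            {
                "vif": {k: (None if v != v else v) for k, v in diag.vif.items()},
                "flagged_pairs": diag.flagged_pairs,
                "constant_columns": diag.constant_columns,
            },
        )
        logger.info("adjusted model fitted with covariates %s", config.spec.covariates)

    # --- stage 6: CEACs -----------------------------------------------------
    curves = [ceac_curve(frame, config.settings, label="overall")]
    if config.spec.covariates:
        curves.append(ceac_curve(frame, config.settings, config.spec, label="adjusted"))
    strat_curves = ceac_by_stratum(frame, config.settings, config.ceac_stratum)
    warnings.extend(strat_curves[0].warnings)
    curves.extend(strat_curves[1:])
    curves_long_frame(curves, ppp_rate=cost.ppp_rate).to_csv(
        register("ceac", outdir / "ceac.csv"), index=False
    )

    interval = ci_from_ceac(curves[0])
    warnings.extend(interval.warnings)
    _write_json(
        register("ceac_ci", outdir / "ceac_ci.json"),
        dataclasses.asdict(interval),
    )
    logger.info(
        "CEAC 95%% interval for the ICER: (%s, %s) CFA",
        interval.ro_low, interval.ro_high,
    )

    # --- stage 7: manifest and summary -------------------------------------
    manifest = {
        "package": "nbcea",
        "version": __version__,
        "seed": config.seed,
        "scenario": config.scenario,
        "input_path": config.input_path,
        "cost": dataclasses.asdict(cost),
        "ro_grid": list(config.settings.ro_grid),
        "regression": dataclasses.asdict(config.spec),
        "strata": list(config.strata),
        "warnings": warnings,
        "outputs": outputs,
        "estimates": {
            "delta_c_cfa": overall.delta_c,
            "delta_e": overall.delta_e,
            "icer_cfa": overall.icer_cfa,
            "icer_intl": overall.icer_intl,
            "inb_at_ro0_cfa": simple_grid[0].delta if simple_grid else None,
            "ci_ro_low_cfa": interval.ro_low,
            "ci_ro_high_cfa": interval.ro_high,
        },
    }
    _write_json(register("manifest", outdir / "manifest.json"), manifest)

    lines = [
        f"nbcea {__version__} run summary",
        f"records: {validation.n_records} ({validation})",
        f"cost increment dC: {overall.delta_c:.1f} CFA",
        f"effect increment dE: {overall.delta_e:.4f} (SE {overall.delta_e_se:.4f})",
        (
            f"ICER: {overall.icer_cfa:.0f} CFA per additional institutional "
            f"delivery (I${overall.icer_intl})"
            if overall.defined
            else f"ICER undefined: {overall.status}"
        ),
        f"quadrant: {overall.quadrant.value}",
        f"95% CEAC interval for the ICER: ({interval.ro_low}, {interval.ro_high}) CFA",
    ]
    (outdir / "summary.txt").write_text("\n".join(lines) + "\n")
    outputs["summary"] = str(outdir / "summary.txt")

    return RunBundle(output_dir=outdir, outputs=outputs, manifest=manifest)
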