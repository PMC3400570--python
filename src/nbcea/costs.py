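"""Societal-perspective cost attribution.

Costs are attributed per household under a societal perspective that sums
household out-of-pocket spending and the health system's incremental cost of
the intervention package:

* intervention arm, institutional delivery: household cost + system
  incremental cost;
* intervention arm, no institutional delivery: system incremental cost only;
* comparison arm, institutional delivery: household cost only;
* comparison arm, no institutional delivery: zero.

The comparison arm carries no system cost because the standard provision of
maternal care is assumed identical in both districts and cancels out of the
increment; only the intervention package's extra system cost remains.  All
arithmetic is kept in CFA; conversion to international dollars (purchasing
power parity) happens only at the reporting boundary.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Mapping, Sequence

import pandas as pd
import yaml

from .errors import ConfigError, RowError
from .records import (
    DEFAULT_DISTANCE_THRESHOLD_KM,
    District,
    HouseholdRecord,
    derive_covariates,
    validate_cohort,
)

#: CFA per international dollar (WHO PPP conversion for the study setting).
DEFAULT_PPP_RATE = 167.0


@dataclass(frozen=True)
class CostConfig:
    """Cost parameters of the analysis.

    ``system_incremental_cost`` is the health-system cost of the intervention
    package per intervention-district household (an input to this analysis,
    estimated by a separate facility costing exercise).  By default it is
    attributed to every intervention-arm household; ``per_delivery_only``
    restricts it to delivering households instead.
    """

    system_incremental_cost: float
    ppp_rate: float = DEFAULT_PPP_RATE
    per_delivery_only: bool = False
    distance_threshold_km: float = DEFAULT_DISTANCE_THRESHOLD_KM

    def __post_init__(self) -> None:
        if self.system_incremental_cost < 0:
            raise ConfigError("system_incremental_cost must be >= 0")
        if self.ppp_rate <= 0:
            raise ConfigError("ppp_rate must be > 0")

    @classmethod
    def from_mapping(cls, mapping: Mapping) -> "CostConfig":
        """Build from a ``cost:`` config block (YAML/JSON)."""
        block = mapping.get("cost", mapping)
        try:
            return cls(
                system_incremental_cost=float(block["system_incremental_cost"]),
                ppp_rate=float(block.get("ppp_rate", DEFAULT_PPP_RATE)),
                per_delivery_only=bool(block.get("per_delivery_only", False)),
                distance_threshold_km=float(
                    block.get("distance_threshold_km", DEFAULT_DISTANCE_THRESHOLD_KM)
                ),
            )
        except KeyError as exc:
            raise ConfigError(f"cost config missing key: {exc}") from exc

    @classmethod
    def from_yaml(cls, source: str | IO[str]) -> "CostConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            with open(source) as fh:
                data = yaml.safe_load(fh)
        return cls.from_mapping(data or {})


def societal_cost(record: HouseholdRecord, config: CostConfig) -> float:
    """Societal cost (CFA) of one household under the attribution rules."""
    delivered = record.institutional_delivery == 1
    if delivered and record.household_cost is None:
        raise RowError(
            f"record {record.id!r}: household_cost required for a delivering household"
        )
    hh = float(record.household_cost) if delivered else 0.0
    if record.district is District.INTERVENTION:
        sys_cost = config.system_incremental_cost
        if config.per_delivery_only and not delivered:
            sys_cost = 0.0
        return hh + sys_cost
    return hh


@dataclass(frozen=True)
class AnalysisRow:
    """A household after cost attribution, ready for regression.

    ``effect`` is the binary effectiveness indicator E_i (institutional
    delivery) and ``societal_cost`` the attributed cost C_i in CFA.
    """

    id: str
    sci: int
    effect: int
    societal_cost: float
    edu_some: int
    dist_far: int
    asset_quintile: int
    asset_dummies: tuple[int, int, int, int]


def build_analysis_rows(
    records: Sequence[HouseholdRecord], config: CostConfig
) -> list[AnalysisRow]:
    """Attribute costs and derive covariates for a validated two-arm cohort."""
    validate_cohort(records)
    rows = []
    for rec in records:
        cov = derive_covariates(rec, config.distance_threshold_km)
        rows.append(
            AnalysisRow(
                id=rec.id,
                sci=cov.sci,
                effect=int(rec.institutional_delivery),
                societal_cost=societal_cost(rec, config),
                edu_some=cov.edu_some,
                dist_far=cov.dist_far,
                asset_quintile=rec.asset_quintile,
                asset_dummies=cov.asset_dummies,
            )
        )
    return rows


#: Column order of the analysis frame shared by the ICER/regression/CEAC layers.
ANALYSIS_COLUMNS = (
    "id",
    "sci",
    "effect",
    "societal_cost",
    "edu_some",
    "dist_far",
    "asset_quintile",
    "asset_q2",
    "asset_q3",
    "asset_q4",
    "asset_q5",
)


def analysis_frame(rows: Sequence[AnalysisRow] | pd.DataFrame) -> pd.DataFrame:
    """Analysis rows as a DataFrame (idempotent on an already-built frame)."""
    if isinstance(rows, pd.DataFrame):
        missing = [c for c in ANALYSIS_COLUMNS if c not in rows.columns and c != "id"]
        if missing:
            raise ConfigError(f"analysis frame missing column(s): {missing}")
        return rows
    data = {
        "id": [r.id for r in rows],
        "sci": [r.sci for r in rows],
        "effect": [r.effect for r in rows],
        "societal_cost": [r.societal_cost for r in rows],
        "edu_some": [r.edu_some for r in rows],
        "dist_far": [r.dist_far for r in rows],
        "asset_quintile": [r.asset_quintile for r in rows],
    }
    for i, col in enumerate(("asset_q2", "asset_q3", "asset_q4", "asset_q5")):
        data[col] = [r.asset_dummies[i] for r in rows]
    return pd.DataFrame(data)


def to_international_dollars(amount_cfa: float, config: CostConfig) -> float:
    """Convert CFA to international dollars at the configured PPP rate."""
    return amount_cfa / config.ppp_rate


def round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (reporting rule)."""
    return int(x + 0.5) if x >= 0 else -int(-x + 0.5)


def intl_dollars_rounded(amount_cfa: float, config: CostConfig) -> int:
    """Reporting-layer I$ figure: converted then integer-rounded."""
    return round_half_away(to_international_dollars(amount_cfa, config))
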