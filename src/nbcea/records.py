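"""Household survey records: schema, CSV I/O, validation and derived covariates.

The unit of observation is one surveyed household with a recent delivery.
Each record carries the study arm (``district``), the binary effectiveness
indicator (``institutional_delivery``: did the birth take place in a health
facility), the household's out-of-pocket cost for that delivery, and the
covariates used in subgroup and adjusted analyses: distance to the nearest
health facility, education of the household head (collapsed to none/some),
and asset-ownership quintile as a wealth proxy.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, fields
from enum import Enum
from typing import IO, Iterable, Sequence

import pandas as pd

from .errors import CohortError, RowError, SchemaError

logger = logging.getLogger(__name__)

#: Distance (km) above which a household counts as "far" from a facility.
DEFAULT_DISTANCE_THRESHOLD_KM = 5.0


class District(str, Enum):
    """Study arm: intervention district vs comparison (status quo) district."""

    INTERVENTION = "intervention"
    COMPARISON = "comparison"


class Education(str, Enum):
    """Education of the household head, collapsed to none vs at least primary."""

    NONE = "none"
    SOME = "some"


@dataclass
class HouseholdRecord:
    """One surveyed household.

    ``household_cost`` is the out-of-pocket cost (CFA) of the institutional
    delivery; it is required when ``institutional_delivery`` is 1 and ignored
    otherwise.  ``revenue``, ``family_size`` and ``perinatal_death`` are
    optional context fields that take no part in the core analysis.
    """

    id: str
    district: District
    institutional_delivery: int
    distance_km: float
    education_head: Education
    asset_quintile: int
    household_cost: float | None = None
    revenue: float | None = None
    family_size: int | None = None
    perinatal_death: int | None = None

    def __post_init__(self) -> None:
        self.district = District(self.district)
        self.education_head = Education(self.education_head)

    def problems(self, strict: bool = True) -> list[str]:
        """Return invariant violations for this record (empty = valid)."""
        out: list[str] = []
        if self.institutional_delivery not in (0, 1):
            out.append(f"institutional_delivery must be 0/1, got {self.institutional_delivery!r}")
        if not (self.distance_km >= 0):
            out.append(f"distance_km must be >= 0, got {self.distance_km!r}")
        if self.asset_quintile not in (1, 2, 3, 4, 5):
            out.append(f"asset_quintile must be in 1..5, got {self.asset_quintile!r}")
        if self.institutional_delivery == 1:
            if self.household_cost is None:
                if strict:
                    out.append("household_cost missing for a delivering household")
            elif self.household_cost < 0:
                out.append(f"household_cost must be >= 0, got {self.household_cost!r}")
        if self.revenue is not None and self.revenue < 0:
            out.append(f"revenue must be >= 0, got {self.revenue!r}")
        if self.family_size is not None and self.family_size < 1:
            out.append(f"family_size must be >= 1, got {self.family_size!r}")
        if self.perinatal_death not in (None, 0, 1):
            out.append(f"perinatal_death must be 0/1, got {self.perinatal_death!r}")
        return out

    def validate(self, strict: bool = True) -> None:
        problems = self.problems(strict=strict)
        if problems:
            raise RowError(f"record {self.id!r}: " + "; ".join(problems))


@dataclass(frozen=True)
class CovariateVector:
    """Regression covariates derived from a record.

    ``sci`` is the treatment dummy (1 = intervention district), ``dist_far``
    flags households more than the distance threshold from a facility, and
    the four asset dummies use quintile 1 as the reference category.
    """

    sci: int
    edu_some: int
    dist_far: int
    asset_dummies: tuple[int, int, int, int]  # quintiles 2..5; q1 is reference


def derive_covariates(
    record: HouseholdRecord,
    distance_threshold_km: float = DEFAULT_DISTANCE_THRESHOLD_KM,
) -> CovariateVector:
    """Derive the covariate vector for a validated record.

    The distance boundary is assigned to the near stratum: ``dist_far`` is 1
    only when ``distance_km`` strictly exceeds the threshold (a household at
    exactly 5 km counts as near).
    """
    q = record.asset_quintile
    return CovariateVector(
        sci=int(record.district is District.INTERVENTION),
        edu_some=int(record.education_head is Education.SOME),
        dist_far=int(record.distance_km > distance_threshold_km),
        asset_dummies=tuple(int(q == k) for k in (2, 3, 4, 5)),
    )


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

MANDATORY_COLUMNS = (
    "id",
    "district",
    "institutional_delivery",
    "household_cost",
    "distance_km",
    "education_head",
    "asset_quintile",
)
OPTIONAL_COLUMNS = ("revenue", "family_size", "perinatal_death")


@dataclass
class ParseReport:
    """What happened while reading a household table."""

    n_rows: int = 0
    n_parsed: int = 0
    n_dropped: int = 0
    n_imputed_costs: int = 0
    warnings: list[str] = field(default_factory=list)
    row_errors: list[str] = field(default_factory=list)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, str) and value.strip() == ""):
        return None
    if isinstance(value, float) and math.isnan(value):
        return None
    return float(value)


def _opt_int(value) -> int | None:
    v = _opt_float(value)
    return None if v is None else int(v)


def read_household_table(
    source: str | IO[str] | IO[bytes], strict: bool = True
) -> tuple[list[HouseholdRecord], ParseReport]:
    """Read a household CSV into validated records.

    Parameters
    ----------
    source
        Path, text stream or byte stream of a UTF-8, comma-delimited CSV
        whose header uses the canonical column names.  Unknown columns are
        ignored.
    strict
        In strict mode any malformed row — including a delivering household
        with a missing cost — raises :class:`RowError`.  In lenient mode
        malformed rows are dropped (and listed in the report) and missing
        delivery costs are imputed with the arm-specific mean of observed
        delivery costs, with a logged warning.

    Returns
    -------
    (records, report)
        Row order is preserved.
    """
    df = pd.read_csv(source, dtype=str, keep_default_na=False)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")

    report = ParseReport(n_rows=len(df))
    records: list[HouseholdRecord] = []
    pending_costs: list[HouseholdRecord] = []  # lenient-mode imputation queue

    for pos, raw in enumerate(df.to_dict(orient="records")):
        label = raw.get("id") or f"row {pos + 2}"  # header is line 1
        try:
            rec = HouseholdRecord(
                id=str(raw["id"]),
                district=District(raw["district"].strip().lower()),
                institutional_delivery=int(raw["institutional_delivery"]),
                distance_km=float(raw["distance_km"]),
                education_head=Education(raw["education_head"].strip().lower()),
                asset_quintile=int(raw["asset_quintile"]),
                household_cost=_opt_float(raw.get("household_cost")),
                revenue=_opt_float(raw.get("revenue")),
                family_size=_opt_int(raw.get("family_size")),
                perinatal_death=_opt_int(raw.get("perinatal_death")),
            )
        except (ValueError, TypeError) as exc:
            msg = f"row {label}: unparseable field ({exc})"
            if strict:
                raise RowError(msg) from exc
            report.row_errors.append(msg)
            report.n_dropped += 1
            continue

        problems = rec.problems(strict=True)
        cost_missing = (
            rec.institutional_delivery == 1 and rec.household_cost is None
        )
        if problems and not (not strict and cost_missing and len(problems) == 1):
            msg = f"row {label}: " + "; ".join(problems)
            if strict:
                raise RowError(msg)
            report.row_errors.append(msg)
            report.n_dropped += 1
            continue
        if cost_missing:
            pending_costs.append(rec)
        records.append(rec)

    if pending_costs:
        for arm in District:
            observed = [
                r.household_cost
                for r in records
                if r.district is arm
                and r.institutional_delivery == 1
                and r.household_cost is not None
            ]
            todo = [r for r in pending_costs if r.district is arm]
            if not todo:
                continue
            if not observed:
                msg = (
                    f"cannot impute household_cost in arm {arm.value!r}: "
                    "no observed delivery costs"
                )
                raise RowError(msg)
            mean_cost = float(sum(observed) / len(observed))
            for r in todo:
                r.household_cost = mean_cost
                report.n_imputed_costs += 1
            warning = (
                f"imputed {len(todo)} missing delivery cost(s) in arm "
                f"{arm.value!r} with the arm mean {mean_cost:.2f} CFA"
            )
            report.warnings.append(warning)
            logger.warning(warning)

    report.n_parsed = len(records)
    return records, report


def write_household_table(records: Iterable[HouseholdRecord], dest: str | IO[str]) -> None:
    """Write records to the canonical CSV dialect (round-trips with the reader)."""
    columns = [f.name for f in fields(HouseholdRecord)]
    own = isinstance(dest, (str, bytes))
    handle: IO[str] = open(dest, "w", newline="") if own else dest  # type: ignore[arg-type]
    try:
        writer = csv.writer(handle)
        writer.writerow(columns)
        for rec in records:
            row = []
            for col in columns:
                value = getattr(rec, col)
                if value is None:
                    row.append("")
                elif isinstance(value, Enum):
                    row.append(value.value)
                else:
                    row.append(value)
            writer.writerow(row)
    finally:
        if own:
            handle.close()


def records_to_frame(records: Sequence[HouseholdRecord]) -> pd.DataFrame:
    """Raw records as a DataFrame (enums as their string values)."""
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "district": [r.district.value for r in records],
            "institutional_delivery": [r.institutional_delivery for r in records],
            "household_cost": [r.household_cost for r in records],
            "distance_km": [r.distance_km for r in records],
            "education_head": [r.education_head.value for r in records],
            "asset_quintile": [r.asset_quintile for r in records],
        }
    )


# ---------------------------------------------------------------------------
# Cohort validation
# ---------------------------------------------------------------------------


@dataclass
class ArmSummary:
    n: int
    n_deliveries: int
    delivery_proportion: float


@dataclass
class ValidationReport:
    arms: dict[str, ArmSummary]
    missingness: dict[str, int]
    n_records: int

    def __str__(self) -> str:  # human-readable one-liner per arm
        parts = [
            f"{name}: n={s.n}, deliveries={s.n_deliveries} ({s.delivery_proportion:.1%})"
            for name, s in self.arms.items()
        ]
        return "; ".join(parts)


def validate_cohort(records: Sequence[HouseholdRecord]) -> ValidationReport:
    """Cohort-level checks: both arms present, per-arm counts and missingness.

    Raises :class:`CohortError` when either arm is empty — every downstream
    increment (cost, effect, net benefit) is undefined on a single arm.
    """
    arms: dict[str, ArmSummary] = {}
    for arm in District:
        members = [r for r in records if r.district is arm]
        if not members:
            raise CohortError(
                f"arm {arm.value!r} is empty: incremental quantities are undefined"
            )
        n_deliv = sum(r.institutional_delivery for r in members)
        arms[arm.value] = ArmSummary(
            n=len(members),
            n_deliveries=n_deliv,
            delivery_proportion=n_deliv / len(members),
        )
    missingness = {
        "household_cost": sum(
            1
            for r in records
            if r.institutional_delivery == 1 and r.household_cost is None
        ),
        "revenue": sum(1 for r in records if r.revenue is None),
        "family_size": sum(1 for r in records if r.family_size is None),
        "perinatal_death": sum(1 for r in records if r.perinatal_death is None),
    }
    return ValidationReport(arms=arms, missingness=missingness, n_records=len(records))
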