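"""Domain types, tabular I/O and configuration for the income/CE pipeline.

The pipeline compares three instruments of household income assessment for
the same patient: direct self-report, the International Wealth Index (IWI,
a twelve-item asset score converted to income) and a picture-catalogue
("Dollar Street" style) estimator.  This module holds the patient-level
record types, the cohort CSV reader/writer and the economic configuration
(PPP factor, CPI ratio) every currency conversion runs through.

Missing data policy: an instrument that was not completed stays missing —
derived incomes are never imputed, and analyses use complete pairs with
per-instrument denominators.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, fields, replace
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

log = logging.getLogger(__name__)

QUALITY_LEVELS = ("low", "medium", "high")

#: CSV column -> HouseholdAssets field
ASSET_COLUMN_FIELDS = {
    "tv": "has_tv",
    "refrigerator": "has_refrigerator",
    "phone": "has_phone",
    "car": "has_car",
    "bicycle": "has_bicycle",
    "cheap_utensils": "has_cheap_utensils",
    "expensive_utensils": "has_expensive_utensils",
    "electricity": "has_electricity",
    "floor_quality": "floor_quality",
    "toilet_quality": "toilet_quality",
    "rooms_category": "rooms_category",
    "water_quality": "water_quality",
}
BOOLEAN_ASSET_COLUMNS = (
    "tv", "refrigerator", "phone", "car", "bicycle",
    "cheap_utensils", "expensive_utensils", "electricity",
)
CATEGORICAL_ASSET_COLUMNS = (
    "floor_quality", "toilet_quality", "rooms_category", "water_quality",
)

#: CSV column -> GapminderSelection field
GAPMINDER_COLUMN_FIELDS = {
    "gm_house": "house_id",
    "gm_kitchen": "kitchen_id",
    "gm_floor": "floor_id",
    "gm_toilet": "toilet_id",
    "gm_bed": "bed_id",
}

OOP_COLUMN_FIELDS = {
    "oop_direct_medical": "direct_medical",
    "oop_direct_nonmedical": "direct_non_medical",
    "oop_indirect": "indirect",
    "oop_total": "total",
}

DEMOGRAPHIC_COLUMNS = (
    "age_band", "sex", "education", "job_skill", "household_size",
    "distance_band", "hospital_type", "cancer_site", "cancer_stage",
    "treatment_intent",
)

COHORT_COLUMNS = (
    ("patient_id", "self_income_inr")
    + BOOLEAN_ASSET_COLUMNS
    + CATEGORICAL_ASSET_COLUMNS
    + tuple(GAPMINDER_COLUMN_FIELDS)
    + tuple(OOP_COLUMN_FIELDS)
)


class ConfigError(ValueError):
    """A configuration value failed validation."""


class RowError(ValueError):
    """A cohort CSV row cannot be turned into a PatientRecord."""


@dataclass(frozen=True)
class HouseholdAssets:
    """Answers to the twelve IWI household items, already recoded to the
    score vocabulary (booleans for durables/electricity, ordered
    low/medium/high for housing quality, rooms binned 0-1/2/3+)."""

    has_tv: bool
    has_refrigerator: bool
    has_phone: bool
    has_car: bool
    has_bicycle: bool
    has_cheap_utensils: bool
    has_expensive_utensils: bool
    has_electricity: bool
    floor_quality: str
    toilet_quality: str
    rooms_category: str
    water_quality: str

    def __post_init__(self) -> None:
        for name in ("floor_quality", "toilet_quality", "rooms_category",
                     "water_quality"):
            value = getattr(self, name)
            if value not in QUALITY_LEVELS:
                raise ValueError(
                    f"{name}={value!r} not one of {QUALITY_LEVELS}")


@dataclass(frozen=True)
class GapminderSelection:
    """The five picture identifiers a patient matched to their household."""

    house_id: str
    kitchen_id: str
    floor_id: str
    toilet_id: str
    bed_id: str


@dataclass(frozen=True)
class OopPayments:
    """Out-of-pocket cancer-care payments (INR) over the costing window.

    Components are optional; when any component is present the total must
    equal the sum of the present components.
    """

    direct_medical: float | None = None
    direct_non_medical: float | None = None
    indirect: float | None = None
    total: float | None = None

    def __post_init__(self) -> None:
        parts = [self.direct_medical, self.direct_non_medical, self.indirect]
        for name, value in zip(
                ("direct_medical", "direct_non_medical", "indirect", "total"),
                parts + [self.total]):
            if value is not None and value < 0:
                raise ValueError(f"OOP {name} must be >= 0, got {value}")
        present = [p for p in parts if p is not None]
        if present:
            component_sum = float(sum(present))
            if self.total is None:
                object.__setattr__(self, "total", component_sum)
            elif abs(self.total - component_sum) > 0.5:
                raise ValueError(
                    f"OOP total {self.total} inconsistent with component "
                    f"sum {component_sum}")


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    self_reported_monthly_income: float | None = None
    assets: HouseholdAssets | None = None
    selection: GapminderSelection | None = None
    oop: OopPayments | None = None
    demographics: Mapping[str, str] | None = None

    def __post_init__(self) -> None:
        income = self.self_reported_monthly_income
        if income is not None and income < 0:
            raise ValueError(
                f"{self.patient_id}: self-reported income must be >= 0")
        if income is None and self.assets is None and self.selection is None:
            raise ValueError(
                f"{self.patient_id}: no income instrument present")


@dataclass(frozen=True)
class EconomicConfig:
    """Currency constants for converting base-year USD/day to target-year
    local currency per month.

    ppp_lcu_per_usd is the USD -> local currency multiplier applied to the
    dollar-denominated instruments; cpi_ratio_target_over_base inflates the
    base-year (2015) IWI income to the survey year.  days_per_month defaults
    to 365.25/12.
    """

    ppp_lcu_per_usd: float = 74.0
    cpi_ratio_target_over_base: float = 1.306
    days_per_month: float = 30.44
    base_year: int = 2015
    target_year: int = 2021

    def __post_init__(self) -> None:
        for name in ("ppp_lcu_per_usd", "cpi_ratio_target_over_base",
                     "days_per_month"):
            value = getattr(self, name)
            if not value > 0:
                raise ConfigError(
                    f"economic.{name} must be strictly positive, got {value}")


# ---------------------------------------------------------------------------
# configuration loading


@dataclass
class AnalysisConfig:
    """Economic + CE + generator configuration with per-key provenance
    ("user" if supplied in the file, "default" otherwise)."""

    economic: EconomicConfig
    ce: Any
    generator: Any
    provenance: dict[str, str] = field(default_factory=dict)


def _build_section(cls, section: str, data: Mapping[str, Any] | None,
                   provenance: dict[str, str]):
    data = dict(data or {})
    known = {f.name for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            warnings.warn(f"config: unknown key {section}.{key} ignored")
            continue
        kwargs[key] = value
    obj = cls(**kwargs)
    for name in known:
        provenance[f"{section}.{name}"] = (
            "user" if name in kwargs else "default")
    return obj


def load_config(path: str | Path | None = None) -> AnalysisConfig:
    """Load a YAML/JSON config with ``economic``, ``ce`` and ``generator``
    sections; absent keys fall back to documented defaults and the
    provenance of every constant is recorded."""
    from .catastrophic_expenditure import CeConfig
    from .synthetic_cohort import GeneratorConfig

    raw: Mapping[str, Any] | None = None
    if path is not None:
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        raw = yaml.safe_load(path.read_text(encoding="utf-8"))
        if raw is None:
            log.info("config %s is empty: all defaults in effect", path)
        elif not isinstance(raw, Mapping):
            raise ConfigError(f"config root must be a mapping, got {type(raw)}")
    raw = dict(raw or {})
    for section in set(raw) - {"economic", "ce", "generator"}:
        warnings.warn(f"config: unknown section {section!r} ignored")

    provenance: dict[str, str] = {}
    econ = _build_section(EconomicConfig, "economic", raw.get("economic"),
                          provenance)
    ce = _build_section(CeConfig, "ce", raw.get("ce"), provenance)
    gen = _build_section(GeneratorConfig, "generator", raw.get("generator"),
                         provenance)
    n_default = sum(1 for v in provenance.values() if v == "default")
    log.info("config loaded: %d keys from file, %d defaults",
             len(provenance) - n_default, n_default)
    return AnalysisConfig(economic=econ, ce=ce, generator=gen,
                          provenance=provenance)


# ---------------------------------------------------------------------------
# cohort CSV I/O

_TRUE = {"1", "true", "yes", "y"}
_FALSE = {"0", "false", "no", "n"}


def _parse_bool(cell: str, column: str) -> bool:
    lowered = cell.strip().lower()
    if lowered in _TRUE:
        return True
    if lowered in _FALSE:
        return False
    raise RowError(f"{column}: {cell!r} is not a recognised boolean")


def _parse_money(cell: str, column: str) -> float:
    try:
        value = float(cell)
    except ValueError:
        raise RowError(f"{column}: {cell!r} is not a number") from None
    if value < 0:
        raise RowError(f"{column}: negative amount {value}")
    return value


def _assets_from_row(row: Mapping[str, str]) -> HouseholdAssets | None:
    cells = {col: row.get(col, "").strip() for col in ASSET_COLUMN_FIELDS}
    present = [col for col, cell in cells.items() if cell != ""]
    if not present:
        return None
    if len(present) < len(cells):
        missing = sorted(set(cells) - set(present))
        warnings.warn(
            f"partial asset block (missing {', '.join(missing)}); "
            "treated as instrument-level missing")
        return None
    kwargs: dict[str, Any] = {}
    for col, field_name in ASSET_COLUMN_FIELDS.items():
        cell = cells[col]
        if col in BOOLEAN_ASSET_COLUMNS:
            kwargs[field_name] = _parse_bool(cell, col)
        else:
            if cell not in QUALITY_LEVELS:
                raise RowError(f"{col}: {cell!r} not one of {QUALITY_LEVELS}")
            kwargs[field_name] = cell
    return HouseholdAssets(**kwargs)


def _selection_from_row(row: Mapping[str, str]) -> GapminderSelection | None:
    cells = {col: row.get(col, "").strip() for col in GAPMINDER_COLUMN_FIELDS}
    present = [col for col, cell in cells.items() if cell != ""]
    if not present:
        return None
    if len(present) < len(cells):
        warnings.warn("partial picture selection; treated as missing")
        return None
    return GapminderSelection(**{
        field_name: cells[col]
        for col, field_name in GAPMINDER_COLUMN_FIELDS.items()})


def _oop_from_row(row: Mapping[str, str]) -> OopPayments | None:
    kwargs: dict[str, float] = {}
    for col, field_name in OOP_COLUMN_FIELDS.items():
        cell = row.get(col, "").strip()
        if cell != "":
            kwargs[field_name] = _parse_money(cell, col)
    if not kwargs:
        return None
    return OopPayments(**kwargs)


def _record_from_row(row: Mapping[str, str]) -> PatientRecord:
    patient_id = row.get("patient_id", "").strip()
    if not patient_id:
        raise RowError("empty patient_id")
    income_cell = row.get("self_income_inr", "").strip()
    income = (_parse_money(income_cell, "self_income_inr")
              if income_cell != "" else None)
    demographics = {
        col: row[col].strip() for col in DEMOGRAPHIC_COLUMNS
        if row.get(col, "").strip() != ""} or None
    try:
        return PatientRecord(
            patient_id=patient_id,
            self_reported_monthly_income=income,
            assets=_assets_from_row(row),
            selection=_selection_from_row(row),
            oop=_oop_from_row(row),
            demographics=demographics,
        )
    except ValueError as exc:  # invariant violations become row rejections
        raise RowError(str(exc)) from exc


def read_cohort(path: str | Path) -> list[PatientRecord]:
    """Read a cohort CSV (UTF-8, header row, empty cell = missing).

    Malformed rows are rejected with a warning naming the line; duplicate
    patient ids abort the load.  A row-count/missingness summary is logged.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False,
                        encoding="utf-8")
    if "patient_id" not in frame.columns:
        raise ValueError(f"{path}: missing required column patient_id")
    records: list[PatientRecord] = []
    seen: set[str] = set()
    n_rejected = 0
    for position, row in enumerate(frame.to_dict(orient="records")):
        line = position + 2  # header is line 1
        try:
            record = _record_from_row(row)
        except RowError as exc:
            n_rejected += 1
            warnings.warn(f"{path} line {line}: {exc}; row rejected")
            continue
        if record.patient_id in seen:
            raise ValueError(
                f"{path}: duplicate patient_id {record.patient_id!r}")
        seen.add(record.patient_id)
        records.append(record)
    log.info(
        "read %d records from %s (%d rejected; missing: self=%d iwi=%d "
        "gapminder=%d oop=%d)",
        len(records), path, n_rejected,
        sum(r.self_reported_monthly_income is None for r in records),
        sum(r.assets is None for r in records),
        sum(r.selection is None for r in records),
        sum(r.oop is None for r in records),
    )
    return records


def _format_bool(value: bool) -> str:
    return "1" if value else "0"


def records_to_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Flatten records into the canonical cohort CSV layout (strings;
    empty string = missing)."""
    rows = []
    for record in records:
        row: dict[str, str] = {col: "" for col in COHORT_COLUMNS}
        row["patient_id"] = record.patient_id
        if record.self_reported_monthly_income is not None:
            row["self_income_inr"] = repr(
                float(record.self_reported_monthly_income))
        if record.assets is not None:
            for col, field_name in ASSET_COLUMN_FIELDS.items():
                value = getattr(record.assets, field_name)
                row[col] = (_format_bool(value)
                            if col in BOOLEAN_ASSET_COLUMNS else value)
        if record.selection is not None:
            for col, field_name in GAPMINDER_COLUMN_FIELDS.items():
                row[col] = getattr(record.selection, field_name)
        if record.oop is not None:
            for col, field_name in OOP_COLUMN_FIELDS.items():
                value = getattr(record.oop, field_name)
                if value is not None:
                    row[col] = repr(float(value))
        for col in DEMOGRAPHIC_COLUMNS:
            if record.demographics and col in record.demographics:
                row[col] = record.demographics[col]
        rows.append(row)
    columns = list(COHORT_COLUMNS)
    if any(r.demographics for r in records):
        columns += [c for c in DEMOGRAPHIC_COLUMNS
                    if any(r.demographics and c in r.demographics
                           for r in records)]
    return pd.DataFrame(rows, columns=columns, dtype=str).fillna("")


def write_results(records: Sequence[PatientRecord], path: str | Path,
                  derived: pd.DataFrame | None = None) -> Path:
    """Write the cohort (plus optional derived columns keyed by patient_id)
    as CSV.  ``read_cohort(write_results(x))`` round-trips every shared
    field; missing derived values are written as empty cells, never 0."""
    frame = records_to_frame(records)
    if derived is not None:
        extra = derived.copy()
        if "patient_id" not in extra.columns:
            raise ValueError("derived frame must carry patient_id")
        extra["patient_id"] = extra["patient_id"].astype(str)
        frame = frame.merge(extra, on="patient_id", how="left")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    frame.to_csv(path, index=False, na_rep="", encoding="utf-8")
    log.info("wrote %d records to %s", len(frame), path)
    return path
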