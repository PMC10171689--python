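"""International Wealth Index scoring and score-to-income conversion.

The IWI is a 0-100 household wealth score: a constant plus weights for
twelve items (seven consumer durables, electricity, and three-level quality
codes for floor material, toilet facility, room count and water source).
A published log-linear relationship converts the score into an expected
household income in 2015 USD per day,

    income(s) = scale * exp(rate * s),   scale = 1.489056, rate = 0.02918,

which is then turned into target-year local currency per month by
multiplying with days/month, the USD->LCU factor and a CPI ratio.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import numpy as np

from .cohort_model import (
    ASSET_COLUMN_FIELDS,
    BOOLEAN_ASSET_COLUMNS,
    CATEGORICAL_ASSET_COLUMNS,
    QUALITY_LEVELS,
    EconomicConfig,
    HouseholdAssets,
)

log = logging.getLogger(__name__)

#: raw sums may leave [0, 100] by this much (rounding residue of the
#: published weights) without triggering a clamp warning
_CLAMP_WARN_TOL = 1e-3


def _data_path(name: str):
    return resources.files("wealthproxy").joinpath("data", name)


@dataclass(frozen=True)
class IwiWeightTable:
    """Constant + per-item weights defining the 0-100 wealth score."""

    constant: float
    boolean_weights: Mapping[str, float]
    categorical_weights: Mapping[str, Mapping[str, float]]
    schema_version: int = 1

    def __post_init__(self) -> None:
        expected_bool = set(BOOLEAN_ASSET_COLUMNS)
        if set(self.boolean_weights) != expected_bool:
            raise ValueError(
                "boolean weights must cover exactly "
                f"{sorted(expected_bool)}, got {sorted(self.boolean_weights)}")
        expected_cat = set(CATEGORICAL_ASSET_COLUMNS)
        if set(self.categorical_weights) != expected_cat:
            raise ValueError(
                "categorical weights must cover exactly "
                f"{sorted(expected_cat)}")
        for item, levels in self.categorical_weights.items():
            if set(levels) != set(QUALITY_LEVELS):
                raise ValueError(
                    f"{item}: weights required for every level of "
                    f"{QUALITY_LEVELS}")

    @property
    def min_score(self) -> float:
        raw = self.constant + sum(
            min(levels.values())
            for levels in self.categorical_weights.values())
        return float(np.clip(raw, 0.0, 100.0))

    @property
    def max_score(self) -> float:
        raw = (self.constant + sum(self.boolean_weights.values())
               + sum(max(levels.values())
                     for levels in self.categorical_weights.values()))
        return float(np.clip(raw, 0.0, 100.0))

    @classmethod
    def from_json(cls, path: str | Path) -> "IwiWeightTable":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(
            constant=data["constant"],
            boolean_weights=data["boolean_weights"],
            categorical_weights=data["categorical_weights"],
            schema_version=data.get("schema_version", 1),
        )


def load_weight_table(path: str | Path | None = None) -> IwiWeightTable:
    """Load a weight table; without a path, the packaged published weights."""
    if path is not None:
        return IwiWeightTable.from_json(path)
    data = json.loads(_data_path("iwi_weights.json").read_text(encoding="utf-8"))
    return IwiWeightTable(
        constant=data["constant"],
        boolean_weights=data["boolean_weights"],
        categorical_weights=data["categorical_weights"],
        schema_version=data.get("schema_version", 1),
    )


def compute_iwi_score(assets: HouseholdAssets | None,
                      table: IwiWeightTable | None = None) -> float | None:
    """Weighted sum over the twelve items, clamped to [0, 100].

    Missing assets yield a missing score.  Clamping beyond the weight
    table's rounding residue raises a warning.
    """
    if assets is None:
        return None
    if table is None:
        table = load_weight_table()
    raw = table.constant
    for col in BOOLEAN_ASSET_COLUMNS:
        if getattr(assets, ASSET_COLUMN_FIELDS[col]):
            raw += table.boolean_weights[col]
    for col in CATEGORICAL_ASSET_COLUMNS:
        level = getattr(assets, ASSET_COLUMN_FIELDS[col])
        raw += table.categorical_weights[col][level]
    if raw < -_CLAMP_WARN_TOL or raw > 100.0 + _CLAMP_WARN_TOL:
        warnings.warn(
            f"IWI raw score {raw:.3f} outside [0, 100]; clamped "
            "(weight table and recode rubric may be mismatched)")
    return float(np.clip(raw, 0.0, 100.0))


@dataclass(frozen=True)
class IwiIncomeModel:
    """Log-linear score -> income model: scale * exp(rate * score),
    in 2015 USD per day."""

    scale: float = 1.489056
    rate: float = 0.02918

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.rate > 0):
            raise ValueError("scale and rate must be strictly positive")


DEFAULT_INCOME_MODEL = IwiIncomeModel()


def iwi_income_daily_usd(score, model: IwiIncomeModel | None = None):
    """Expected household income (base-year USD/day) at an IWI score.

    Accepts a scalar or array score in [0, 100]; strictly increasing.
    """
    if model is None:
        model = DEFAULT_INCOME_MODEL
    arr = np.asarray(score, dtype=float)
    if np.any((arr < 0) | (arr > 100)) or np.any(np.isnan(arr)):
        raise ValueError("IWI score must lie in [0, 100]")
    out = model.scale * np.exp(model.rate * arr)
    return float(out) if np.isscalar(score) or arr.ndim == 0 else out


def to_monthly_local(daily_usd, econ: EconomicConfig):
    """Convert base-year USD/day to target-year LCU/month:
    daily * days_per_month * ppp_lcu_per_usd * cpi_ratio."""
    arr = np.asarray(daily_usd, dtype=float)
    out = (arr * econ.days_per_month * econ.ppp_lcu_per_usd
           * econ.cpi_ratio_target_over_base)
    return float(out) if np.isscalar(daily_usd) or arr.ndim == 0 else out


def score_to_monthly_inr(score, econ: EconomicConfig,
                         model: IwiIncomeModel | None = None):
    """Composition of the score->USD/day model and the currency pipeline."""
    return to_monthly_local(iwi_income_daily_usd(score, model), econ)


# ---------------------------------------------------------------------------
# raw-response recoding


@dataclass(frozen=True)
class RecodeRubric:
    """Maps raw survey vocabulary to ordered quality levels.

    ``floor``/``toilet``/``water`` map lowercased raw strings to a level;
    rooms are binned by count (``<= rooms_low_max`` low, ``<= rooms_medium_max``
    medium, above high).
    """

    floor: Mapping[str, str]
    toilet: Mapping[str, str]
    water: Mapping[str, str]
    rooms_low_max: int = 1
    rooms_medium_max: int = 2
    schema_version: int = 1

    def rooms_level(self, rooms: int) -> str:
        if rooms < 0:
            raise ValueError(f"negative room count {rooms}")
        if rooms <= self.rooms_low_max:
            return "low"
        if rooms <= self.rooms_medium_max:
            return "medium"
        return "high"


def _invert_levels(block: Mapping[str, list[str]]) -> dict[str, str]:
    lookup: dict[str, str] = {}
    for level, values in block.items():
        if level == "description":
            continue
        for value in values:
            lookup[value.lower()] = level
    return lookup


def load_recode_rubric(path: str | Path | None = None) -> RecodeRubric:
    if path is not None:
        data = json.loads(Path(path).read_text(encoding="utf-8"))
    else:
        data = json.loads(
            _data_path("recode_rubric.json").read_text(encoding="utf-8"))
    return RecodeRubric(
        floor=_invert_levels(data["floor_material"]),
        toilet=_invert_levels(data["toilet_facility"]),
        water=_invert_levels(data["water_source"]),
        rooms_low_max=data["rooms"]["low_max"],
        rooms_medium_max=data["rooms"]["medium_max"],
        schema_version=data.get("schema_version", 1),
    )


_RAW_BOOLEAN_KEYS = ("tv", "refrigerator", "phone", "car", "bicycle",
                     "cheap_utensils", "expensive_utensils", "electricity")

_TRUTHY = {True, 1, "1", "true", "yes", "y"}
_FALSY = {False, 0, "0", "false", "no", "n"}


def recode_assets(raw: Mapping[str, Any],
                  rubric: RecodeRubric | None = None) -> HouseholdAssets | None:
    """Map raw survey answers to a :class:`HouseholdAssets` block.

    Expected keys: the eight durables/electricity booleans, plus
    ``floor_material``, ``toilet_facility``, ``water_source`` (strings in
    the rubric vocabulary) and ``rooms`` (a count).  All keys absent ->
    missing block; any unknown raw value -> missing block with a warning.
    """
    if rubric is None:
        rubric = load_recode_rubric()
    raw = {k: v for k, v in raw.items() if v is not None and v != ""}
    if not raw:
        return None

    kwargs: dict[str, Any] = {}
    for key in _RAW_BOOLEAN_KEYS:
        if key not in raw:
            warnings.warn(f"recode: missing answer for {key!r}; "
                          "assets treated as missing")
            return None
        value = raw[key]
        if isinstance(value, str):
            value = value.strip().lower()
        if value in _TRUTHY:
            kwargs[ASSET_COLUMN_FIELDS[key]] = True
        elif value in _FALSY:
            kwargs[ASSET_COLUMN_FIELDS[key]] = False
        else:
            warnings.warn(f"recode: unrecognised answer {raw[key]!r} for "
                          f"{key!r}; assets treated as missing")
            return None

    for key, lookup, field_name in (
            ("floor_material", rubric.floor, "floor_quality"),
            ("toilet_facility", rubric.toilet, "toilet_quality"),
            ("water_source", rubric.water, "water_quality")):
        if key not in raw:
            warnings.warn(f"recode: missing answer for {key!r}; "
                          "assets treated as missing")
            return None
        level = lookup.get(str(raw[key]).strip().lower())
        if level is None:
            warnings.warn(f"recode: unknown {key} value {raw[key]!r}; "
                          "assets treated as missing")
            return None
        kwargs[field_name] = level

    if "rooms" not in raw:
        warnings.warn("recode: missing answer for 'rooms'; "
                      "assets treated as missing")
        return None
    try:
        rooms = int(raw["rooms"])
        kwargs["rooms_category"] = rubric.rooms_level(rooms)
    except (TypeError, ValueError):
        warnings.warn(f"recode: unrecognised room count {raw['rooms']!r}; "
                      "assets treated as missing")
        return None
    return HouseholdAssets(**kwargs)
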