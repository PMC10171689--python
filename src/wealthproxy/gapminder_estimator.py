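"""Picture-catalogue (Dollar Street style) household income estimation.

A catalogue holds, for each of five categories (house, kitchen, floor,
toilet, bed), pictures tagged with the monthly income (base USD) of the
household they were photographed in.  A patient picks the most similar
picture per category; the income estimate is the arithmetic mean of the
five matched incomes multiplied by the USD->LCU factor.  Unlike the wealth
score conversion, no CPI term is applied: the catalogue incomes are taken
at face value in the survey year.
"""

from __future__ import annotations

import json
import logging
import warnings
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort_model import EconomicConfig, GapminderSelection

log = logging.getLogger(__name__)

CATEGORIES = ("house", "kitchen", "floor", "toilet", "bed")

_SELECTION_FIELDS = {
    "house": "house_id",
    "kitchen": "kitchen_id",
    "floor": "floor_id",
    "toilet": "toilet_id",
    "bed": "bed_id",
}


class GapminderCatalogue:
    """Validated picture-income catalogue.

    Parameters
    ----------
    entries
        Mapping of category -> sequence of ``(picture_id, monthly_income_usd)``
        pairs.  Every one of the five categories must be present and
        non-empty; picture ids must be unique within a category; incomes
        strictly positive.  Distinct pictures may share an income.
    """

    def __init__(self, entries: Mapping[str, Sequence[tuple[str, float]]]):
        missing = set(CATEGORIES) - set(entries)
        if missing:
            raise ValueError(f"catalogue missing categories: {sorted(missing)}")
        unknown = set(entries) - set(CATEGORIES)
        if unknown:
            raise ValueError(f"unknown catalogue categories: {sorted(unknown)}")
        self._by_id: dict[str, dict[str, float]] = {}
        self._sorted_log: dict[str, np.ndarray] = {}
        self._sorted_ids: dict[str, list[str]] = {}
        for category in CATEGORIES:
            pairs = list(entries[category])
            if not pairs:
                raise ValueError(f"catalogue category {category!r} is empty")
            ids = [str(pid) for pid, _ in pairs]
            incomes = np.asarray([inc for _, inc in pairs], dtype=float)
            if len(set(ids)) != len(ids):
                dupes = sorted({i for i in ids if ids.count(i) > 1})
                raise ValueError(
                    f"duplicate picture ids in {category!r}: {dupes}")
            if np.any(incomes <= 0) or np.any(~np.isfinite(incomes)):
                raise ValueError(
                    f"catalogue category {category!r} has non-positive income")
            self._by_id[category] = dict(zip(ids, incomes))
            order = np.argsort(incomes, kind="stable")
            self._sorted_log[category] = np.log(incomes[order])
            self._sorted_ids[category] = [ids[i] for i in order]

    def __len__(self) -> int:
        return sum(len(v) for v in self._by_id.values())

    @property
    def categories(self) -> tuple[str, ...]:
        return CATEGORIES

    def income_for(self, category: str, picture_id: str) -> float | None:
        """Monthly income (base USD) matched to a picture, or None."""
        return self._by_id[category].get(str(picture_id))

    def nearest_pictures(self, category: str, usd) -> np.ndarray:
        """Picture id(s) whose tagged income is nearest in log space.

        Ties between the two bracketing pictures break toward the lower
        income.  Vectorised over ``usd``.
        """
        targets = np.log(np.asarray(usd, dtype=float))
        logs = self._sorted_log[category]
        idx = np.searchsorted(logs, targets)
        idx = np.clip(idx, 1, len(logs) - 1) if len(logs) > 1 else idx * 0
        if len(logs) > 1:
            lower = idx - 1
            pick_lower = (targets - logs[lower]) <= (logs[idx] - targets)
            idx = np.where(pick_lower, lower, idx)
        ids = np.asarray(self._sorted_ids[category], dtype=object)
        out = ids[np.atleast_1d(idx)]
        return out if np.ndim(usd) else out[0]

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"category": category, "picture_id": pid,
             "monthly_income_usd": income}
            for category in CATEGORIES
            for pid, income in self._by_id[category].items()]
        return pd.DataFrame(rows)


def load_catalogue(path: str | Path) -> GapminderCatalogue:
    """Load a catalogue from CSV (category,picture_id,monthly_income_usd)
    or from JSON ({category: [[picture_id, income], ...]})."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        data = json.loads(path.read_text(encoding="utf-8"))
        entries = {category: [(pid, float(income)) for pid, income in pairs]
                   for category, pairs in data.items()}
        return GapminderCatalogue(entries)
    frame = pd.read_csv(path)
    required = {"category", "picture_id", "monthly_income_usd"}
    if not required.issubset(frame.columns):
        raise ValueError(
            f"catalogue CSV must have columns {sorted(required)}")
    entries = {
        category: list(zip(group["picture_id"].astype(str),
                           group["monthly_income_usd"].astype(float)))
        for category, group in frame.groupby("category", sort=False)}
    return GapminderCatalogue(entries)


def build_synthetic_catalogue(n_per_category: int = 30,
                              low_usd: float = 50.0,
                              high_usd: float = 5000.0) -> GapminderCatalogue:
    """Synthetic catalogue: per category, ``n_per_category`` pictures with
    log-uniformly spaced monthly incomes spanning ``low_usd``..``high_usd``.

    Stands in for the real photo catalogue (identifiers only, no images).
    """
    if n_per_category < 1 or not 0 < low_usd < high_usd:
        raise ValueError("need n_per_category >= 1 and 0 < low < high")
    if n_per_category == 1:
        grid = np.asarray([low_usd])
    else:
        grid = low_usd * (high_usd / low_usd) ** (
            np.arange(n_per_category) / (n_per_category - 1))
    entries = {
        category: [(f"{category}_{i:02d}", float(grid[i]))
                   for i in range(n_per_category)]
        for category in CATEGORIES}
    return GapminderCatalogue(entries)


def default_catalogue() -> GapminderCatalogue:
    """The packaged synthetic catalogue (30 pictures per category)."""
    path = resources.files("wealthproxy").joinpath(
        "data", "gapminder_catalogue.csv")
    with resources.as_file(path) as fp:
        return load_catalogue(fp)


def gapminder_income(selection: GapminderSelection | None,
                     catalogue: GapminderCatalogue,
                     econ: EconomicConfig) -> float | None:
    """Monthly income estimate (LCU): mean of the five matched catalogue
    incomes times the USD->LCU factor.

    Any unresolved picture id makes the whole estimate missing (the
    formula averages exactly five categories).
    """
    if selection is None:
        return None
    matched = []
    for category in CATEGORIES:
        picture_id = getattr(selection, _SELECTION_FIELDS[category])
        income = catalogue.income_for(category, picture_id)
        if income is None:
            warnings.warn(
                f"picture {picture_id!r} not in catalogue category "
                f"{category!r}; estimate treated as missing")
            return None
        matched.append(income)
    return float(np.mean(matched) * econ.ppp_lcu_per_usd)
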