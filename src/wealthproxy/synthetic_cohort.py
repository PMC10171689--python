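"""Calibrated synthetic patient cohorts for the income/CE pipeline.

No patient-level data are deposited for the cohort this package models
(226 colorectal-cancer patients from five Indian tertiary-care hospitals),
so every pipeline stage is exercised on synthetic households engineered to
reproduce the published marginal summaries:

* self-reported income   median 17 350 INR/month (IQR 10 000-40 000)
* IWI-implied income     median 37 491 INR/month (IQR 25 421-61 322)
* picture-tool income    median 51 520 INR/month (IQR 22 120-91 128)
* 6-week OOP expenditure median 202 291 INR      (IQR 107 900-308 010)

Design: one standard-normal latent wealth variable W drives all channels.
Channel c draws Z_c = rho_c W + sqrt(1-rho_c^2) eps_c and maps Z_c through
its fitted log-normal marginal.  The self-report and expenditure channels
emit that value directly; the IWI channel inverts the target income to a
target score and realizes an asset bundle whose recomputed score is close
to the target (greedy acquisition order, deterministic); the picture
channel perturbs the target per category and snaps to the
nearest-log-income picture in the catalogue.  A truth table records every
latent and target for parameter-recovery tests.
"""

from __future__ import annotations

import logging
import warnings
from copy import deepcopy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .cohort_model import (
    ASSET_COLUMN_FIELDS,
    BOOLEAN_ASSET_COLUMNS,
    CATEGORICAL_ASSET_COLUMNS,
    QUALITY_LEVELS,
    EconomicConfig,
    GapminderSelection,
    HouseholdAssets,
    OopPayments,
    PatientRecord,
)
from .gapminder_estimator import CATEGORIES, GapminderCatalogue, default_catalogue
from .iwi_scoring import (
    DEFAULT_INCOME_MODEL,
    IwiIncomeModel,
    IwiWeightTable,
    load_weight_table,
)

log = logging.getLogger(__name__)

#: standard-normal 75th-percentile deviate, z_0.75
Z75 = float(norm.ppf(0.75))


@dataclass(frozen=True)
class LogNormalSpec:
    """Log-normal marginal with the quantile triple it was fitted from."""

    mu: float
    sigma: float
    provenance: tuple[float, float, float] | None = None  # (median, q1, q3)

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")

    @property
    def median(self) -> float:
        return float(np.exp(self.mu))

    @property
    def q1(self) -> float:
        return float(np.exp(self.mu - Z75 * self.sigma))

    @property
    def q3(self) -> float:
        return float(np.exp(self.mu + Z75 * self.sigma))

    def transform(self, z):
        """Quantile transform of standard-normal draws."""
        return np.exp(self.mu + self.sigma * np.asarray(z, dtype=float))


def fit_lognormal_from_quantiles(median: float, q1: float, q3: float
                                 ) -> LogNormalSpec:
    """Closed-form fit: mu = ln(median), sigma = ln(q3/q1) / (2 z_0.75).

    The fitted distribution's median equals the input exactly, and its
    quartile ratio q3/q1 is matched exactly; the individual quartiles are
    reproduced exactly only when the inputs are log-symmetric about the
    median (median = sqrt(q1 q3)).
    """
    if not (q1 > 0 and median > 0 and q3 > 0):
        raise ValueError("quantiles must be strictly positive")
    if not q1 < median < q3:
        raise ValueError(
            f"need q1 < median < q3, got ({q1}, {median}, {q3})")
    return LogNormalSpec(mu=float(np.log(median)),
                         sigma=float(np.log(q3 / q1) / (2 * Z75)),
                         provenance=(median, q1, q3))


#: published median/quartile targets (INR) of the emulated cohort
COHORT_QUANTILES = {
    "self": (17_350.0, 10_000.0, 40_000.0),
    "iwi": (37_491.0, 25_421.0, 61_322.0),
    "gapminder": (51_520.0, 22_120.0, 91_128.0),
    "oop": (202_291.0, 107_900.0, 308_010.0),
}

DEFAULT_MARGINALS = {
    channel: fit_lognormal_from_quantiles(*triple)
    for channel, triple in COHORT_QUANTILES.items()
}

#: Table-1 style category frequencies of the emulated cohort
DEFAULT_DEMOGRAPHICS: dict[str, dict[str, float]] = {
    "age_band": {"18-30": 18, "31-50": 83, "51-70": 96, ">70": 28},
    "sex": {"male": 143, "female": 83},
    "education": {"primary": 51, "secondary": 83, "graduate": 63,
                  "post_graduate": 19, "no_school": 10},
    "job_skill": {"low": 30, "medium": 40, "high": 40, "housewife": 65,
                  "retired": 39, "other": 12},
    "household_size": {"1-3": 60, "4-6": 118, "7-9": 35, "10+": 13},
    "distance_band": {"0-100km": 77, "100-500km": 73, "500-1000km": 10,
                      ">1000km": 66},
    "hospital_type": {"government": 80, "charity_private": 146},
    "cancer_site": {"colon": 108, "rectum": 118},
    "cancer_stage": {"local": 31, "advanced": 195},
    "treatment_intent": {"curative": 187, "palliative": 38},
}


@dataclass
class GeneratorConfig:
    """Study-condition defaults for the synthetic cohort.

    n=226 with one missing IWI response and one missing picture response
    mirrors the emulated cohort's size and completion rates.  The three
    income channels share the wealth latent perfectly (correlation 1.0);
    expenditure is weakly wealth-linked (0.3, an assumption — no joint
    statistic is published).  selection_noise_sigma is the log-scale SD of
    per-category picture-matching noise.
    """

    n: int = 226
    seed: int = 42
    marginals: dict[str, LogNormalSpec] = field(
        default_factory=lambda: dict(DEFAULT_MARGINALS))
    latent_correlations: dict[str, float] = field(
        default_factory=lambda: {"self": 1.0, "iwi": 1.0,
                                 "gapminder": 1.0, "oop": 0.3})
    selection_noise_sigma: float = 0.25
    demographics_frequencies: dict[str, dict[str, float]] | None = field(
        default_factory=lambda: deepcopy(DEFAULT_DEMOGRAPHICS))
    n_missing_iwi: int = 1
    n_missing_gapminder: int = 1

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError(f"n must be >= 1, got {self.n}")
        for channel, rho in self.latent_correlations.items():
            if not -1.0 <= rho <= 1.0:
                raise ValueError(
                    f"latent correlation for {channel!r} outside [-1, 1]")
        if self.selection_noise_sigma < 0:
            raise ValueError("selection_noise_sigma must be >= 0")
        missing = set(COHORT_QUANTILES) - set(self.marginals)
        if missing:
            raise ValueError(f"marginals missing channels {sorted(missing)}")


def invert_income_to_score(monthly_income_inr,
                           econ: EconomicConfig | None = None,
                           model: IwiIncomeModel | None = None):
    """Invert the score->monthly-income composition:
    s = ln(income / (scale * days * ppp * cpi)) / rate, clamped to [0, 100].

    Clamping is reported via a warning carrying the clamp fraction.
    """
    if econ is None:
        econ = EconomicConfig()
    if model is None:
        model = DEFAULT_INCOME_MODEL
    arr = np.asarray(monthly_income_inr, dtype=float)
    if np.any(arr <= 0) or np.any(~np.isfinite(arr)):
        raise ValueError("income must be strictly positive")
    base = (model.scale * econ.days_per_month * econ.ppp_lcu_per_usd
            * econ.cpi_ratio_target_over_base)
    scores = np.log(arr / base) / model.rate
    clamped = (scores < 0) | (scores > 100)
    if np.any(clamped):
        warnings.warn(
            f"{np.mean(clamped):.1%} of incomes imply scores outside "
            "[0, 100]; clamped")
    out = np.clip(scores, 0.0, 100.0)
    return float(out) if arr.ndim == 0 else out


class BundleSynthesizer:
    """Deterministic greedy asset-bundle realization for a target score.

    Acquisition order: starting from the minimum configuration (no
    durables, all housing at 'low'), repeatedly take the largest available
    upgrade that does not overshoot the target (categorical levels upgrade
    stepwise); finally take one extra smallest step if it reduces the
    absolute error.  Bundles are cached per rounded target score.
    """

    #: greedy stops adding steps once within this many points of the target
    tolerance = 2.5

    def __init__(self, table: IwiWeightTable | None = None):
        self.table = table if table is not None else load_weight_table()
        self._cache: dict[float, tuple[HouseholdAssets, float]] = {}
        self._base_score = self.table.constant + sum(
            levels["low"]
            for levels in self.table.categorical_weights.values())
        # upgrade steps: (delta, kind, item, new_level_index)
        self._bool_steps = sorted(
            ((w, "bool", item, None)
             for item, w in self.table.boolean_weights.items()),
            key=lambda s: -s[0])
        self._cat_deltas = {
            item: [levels["medium"] - levels["low"],
                   levels["high"] - levels["medium"]]
            for item, levels in self.table.categorical_weights.items()}

    def bundle(self, target_score: float) -> tuple[HouseholdAssets, float]:
        """Asset bundle and its realized (clamped) score for a target."""
        key = round(float(target_score), 2)
        cached = self._cache.get(key)
        if cached is not None:
            return cached
        owned: set[str] = set()
        cat_level = {item: 0 for item in self._cat_deltas}
        score = self._base_score

        def available():
            for delta, _, item, _ in self._bool_steps:
                if item not in owned and delta > 0:
                    yield delta, "bool", item
            for item, deltas in self._cat_deltas.items():
                level = cat_level[item]
                if level < 2 and deltas[level] > 0:
                    yield deltas[level], "cat", item

        while True:
            gap = key - score
            if gap <= 0:
                break
            fitting = [step for step in available() if step[0] <= gap]
            if not fitting:
                break
            delta, kind, item = max(fitting, key=lambda s: s[0])
            if kind == "bool":
                owned.add(item)
            else:
                cat_level[item] += 1
            score += delta
        # polish: deterministic hill climb on |score - target| over single
        # moves (toggle a durable, shift a categorical one level) and swap
        # moves (one removal paired with one addition)
        while abs(key - score) > self.tolerance / 2:
            singles: list[tuple[float, tuple]] = []
            for delta, _, item, _ in self._bool_steps:
                if item in owned:
                    singles.append((-delta, (("bool", item, 0),)))
                else:
                    singles.append((delta, (("bool", item, 0),)))
            for item, deltas in self._cat_deltas.items():
                level = cat_level[item]
                if level < 2:
                    singles.append((deltas[level], (("cat", item, +1),)))
                if level > 0:
                    singles.append((-deltas[level - 1], (("cat", item, -1),)))
            moves = list(singles)
            removals = [m for m in singles if m[0] < 0]
            additions = [m for m in singles if m[0] > 0]
            for d1, ops1 in removals:
                for d2, ops2 in additions:
                    if ops1[0][1] != ops2[0][1]:
                        moves.append((d1 + d2, ops1 + ops2))
            delta, ops = min(
                moves, key=lambda m: (abs(score + m[0] - key), m[1]))
            if abs(score + delta - key) >= abs(score - key):
                break
            for kind, item, direction in ops:
                if kind == "bool":
                    owned.symmetric_difference_update({item})
                else:
                    cat_level[item] += direction
            score += delta

        kwargs: dict = {}
        for col in BOOLEAN_ASSET_COLUMNS:
            kwargs[ASSET_COLUMN_FIELDS[col]] = col in owned
        for col in CATEGORICAL_ASSET_COLUMNS:
            kwargs[ASSET_COLUMN_FIELDS[col]] = QUALITY_LEVELS[cat_level[col]]
        assets = HouseholdAssets(**kwargs)
        realized = float(np.clip(score, 0.0, 100.0))
        result = (assets, realized)
        self._cache[key] = result
        return result


def _channel_latents(w: np.ndarray, rho: float,
                     rng: np.random.Generator) -> np.ndarray:
    eps = rng.standard_normal(w.size)
    return rho * w + np.sqrt(max(0.0, 1.0 - rho * rho)) * eps


def generate_cohort(gen: GeneratorConfig | None = None,
                    econ: EconomicConfig | None = None,
                    weight_table: IwiWeightTable | None = None,
                    catalogue: GapminderCatalogue | None = None,
                    income_model: IwiIncomeModel | None = None,
                    ) -> tuple[list[PatientRecord], pd.DataFrame]:
    """Generate a seeded synthetic cohort plus its truth table.

    Returns ``(records, truth)`` where ``truth`` holds, per household, the
    shared wealth latent, the channel latents, the target incomes, the
    target and realized IWI scores, and missingness flags.  Runs are
    bit-reproducible for a fixed config (a single seed feeds a documented
    SeedSequence split: latent, self, iwi, gapminder, picture noise, oop,
    demographics, missingness).
    """
    gen = gen if gen is not None else GeneratorConfig()
    econ = econ if econ is not None else EconomicConfig()
    weight_table = (weight_table if weight_table is not None
                    else load_weight_table())
    catalogue = catalogue if catalogue is not None else default_catalogue()
    income_model = (income_model if income_model is not None
                    else DEFAULT_INCOME_MODEL)

    n = gen.n
    streams = np.random.SeedSequence(gen.seed).spawn(8)
    rng_latent, rng_self, rng_iwi, rng_gap, rng_noise, rng_oop, \
        rng_demo, rng_missing = (np.random.default_rng(s) for s in streams)

    w = rng_latent.standard_normal(n)
    z_self = _channel_latents(w, gen.latent_correlations["self"], rng_self)
    z_iwi = _channel_latents(w, gen.latent_correlations["iwi"], rng_iwi)
    z_gap = _channel_latents(w, gen.latent_correlations["gapminder"], rng_gap)
    z_oop = _channel_latents(w, gen.latent_correlations["oop"], rng_oop)

    self_income = gen.marginals["self"].transform(z_self)
    iwi_target_income = gen.marginals["iwi"].transform(z_iwi)
    gap_target_income = gen.marginals["gapminder"].transform(z_gap)
    oop_total = gen.marginals["oop"].transform(z_oop)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clamp fraction logged below
        target_scores = np.asarray(
            invert_income_to_score(iwi_target_income, econ, income_model))
    clamp_fraction = float(np.mean(
        (target_scores <= 0.0) | (target_scores >= 100.0)))
    if clamp_fraction:
        log.info("IWI target scores clamped for %.1f%% of households",
                 100 * clamp_fraction)

    synthesizer = BundleSynthesizer(weight_table)
    bundles = [synthesizer.bundle(s) for s in target_scores]
    assets_list = [b[0] for b in bundles]
    realized_scores = np.asarray([b[1] for b in bundles])

    target_usd = gap_target_income / econ.ppp_lcu_per_usd
    noise = rng_noise.normal(0.0, gen.selection_noise_sigma,
                             size=(n, len(CATEGORIES)))
    picks = {
        category: np.atleast_1d(catalogue.nearest_pictures(
            category, target_usd * np.exp(noise[:, j])))
        for j, category in enumerate(CATEGORIES)}

    demographics: list[dict[str, str] | None] = [None] * n
    if gen.demographics_frequencies:
        demo_values: dict[str, np.ndarray] = {}
        for variable, freqs in gen.demographics_frequencies.items():
            levels = list(freqs)
            probs = np.asarray([freqs[level] for level in levels], float)
            probs = probs / probs.sum()
            idx = rng_demo.choice(len(levels), size=n, p=probs)
            demo_values[variable] = np.asarray(levels, object)[idx]
        demographics = [
            {variable: str(values[i])
             for variable, values in demo_values.items()}
            for i in range(n)]

    n_missing = gen.n_missing_iwi + gen.n_missing_gapminder
    missing_iwi_idx: set[int] = set()
    missing_gap_idx: set[int] = set()
    if 0 < n_missing <= n:
        drawn = rng_missing.choice(n, size=n_missing, replace=False)
        missing_iwi_idx = set(drawn[:gen.n_missing_iwi].tolist())
        missing_gap_idx = set(drawn[gen.n_missing_iwi:].tolist())

    width = max(5, len(str(n)))
    records: list[PatientRecord] = []
    for i in range(n):
        selection = None if i in missing_gap_idx else GapminderSelection(
            house_id=str(picks["house"][i]),
            kitchen_id=str(picks["kitchen"][i]),
            floor_id=str(picks["floor"][i]),
            toilet_id=str(picks["toilet"][i]),
            bed_id=str(picks["bed"][i]))
        records.append(PatientRecord(
            patient_id=f"P{i + 1:0{width}d}",
            self_reported_monthly_income=float(self_income[i]),
            assets=None if i in missing_iwi_idx else assets_list[i],
            selection=selection,
            oop=OopPayments(total=float(oop_total[i])),
            demographics=demographics[i]))

    truth = pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "latent_wealth": w,
        "z_self": z_self, "z_iwi": z_iwi, "z_gapminder": z_gap,
        "z_oop": z_oop,
        "income_self": self_income,
        "target_income_iwi": iwi_target_income,
        "target_score_iwi": target_scores,
        "realized_score_iwi": realized_scores,
        "target_income_gapminder": gap_target_income,
        "oop_total": oop_total,
        "iwi_missing": [i in missing_iwi_idx for i in range(n)],
        "gapminder_missing": [i in missing_gap_idx for i in range(n)],
    })
    log.info("generated %d synthetic households (seed %d)", n, gen.seed)
    return records, truth
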