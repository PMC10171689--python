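"""Catastrophic health expenditure (SDG 3.8.2) classification and rates.

A household experiences catastrophic expenditure (CE) when its
out-of-pocket (OOP) payments for care reach a stated fraction of household
income (default 25%; 10% and 40% are the other conventional thresholds).
Income enters annualized (monthly x 12) and the boundary is inclusive:
OOP >= threshold * 12 * monthly_income.  Cohort rates carry Wilson 95%
confidence intervals and per-instrument denominators (missing instruments
shrink the denominator, never get imputed).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .cohort_model import PatientRecord

log = logging.getLogger(__name__)

MONTHS_PER_YEAR = 12


@dataclass(frozen=True)
class CeConfig:
    """Catastrophic-expenditure definition.

    threshold_fraction: OOP as a fraction of annualized household income
    (0.25 default; 0.10 / 0.40 selectable).  The 40% convention normally
    applies to non-subsistence income; no subsistence deduction is made
    here, so with 0.40 the rate is against total income.
    """

    threshold_fraction: float = 0.25
    income_basis: str = "annualized_monthly"
    boundary_rule: str = "geq"

    def __post_init__(self) -> None:
        if not 0 < self.threshold_fraction < 1:
            raise ValueError(
                f"threshold_fraction must be in (0, 1), got "
                f"{self.threshold_fraction}")
        if self.income_basis != "annualized_monthly":
            raise ValueError(
                f"unsupported income_basis {self.income_basis!r}")
        if self.boundary_rule != "geq":
            raise ValueError(
                f"unsupported boundary_rule {self.boundary_rule!r}")


def total_oop(record: PatientRecord) -> float | None:
    """Total OOP payments: the explicit total when given, else the sum of
    present components; missing when no OOP data exists."""
    if record.oop is None:
        return None
    return record.oop.total  # OopPayments already reconciles components


def classify_catastrophic(oop_total: float | None,
                          monthly_income: float | None,
                          ce: CeConfig | None = None) -> bool | None:
    """CE flag: OOP >= threshold * 12 * monthly income (inclusive boundary).

    Missing inputs give a missing flag.  Zero income is degenerate: any
    positive OOP is catastrophic (flag raised with a warning).
    """
    if ce is None:
        ce = CeConfig()
    if oop_total is None or monthly_income is None:
        return None
    if isinstance(monthly_income, float) and np.isnan(monthly_income):
        return None
    if monthly_income < 0:
        raise ValueError(f"negative monthly income {monthly_income}")
    if monthly_income == 0:
        warnings.warn("zero household income: any positive OOP payment is "
                      "classified catastrophic")
        return oop_total > 0
    cutoff = ce.threshold_fraction * MONTHS_PER_YEAR * monthly_income
    return bool(oop_total >= cutoff)


@dataclass(frozen=True)
class CeResult:
    """Cohort CE rate for one income instrument."""

    instrument: str
    threshold_fraction: float
    n_classified: int
    n_catastrophic: int
    rate: float
    ci_low: float
    ci_high: float

    def as_dict(self) -> dict:
        return {
            "instrument": self.instrument,
            "threshold_fraction": self.threshold_fraction,
            "n_classified": self.n_classified,
            "n_catastrophic": self.n_catastrophic,
            "rate": self.rate, "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def ce_rates(records: Sequence[PatientRecord],
             incomes_by_instrument: Mapping[str, Sequence[float | None]],
             ce: CeConfig | None = None) -> dict[str, CeResult]:
    """CE rate per income instrument with Wilson 95% CI.

    ``incomes_by_instrument`` maps an instrument name to per-patient
    monthly incomes aligned with ``records`` (None/NaN = missing).
    Instruments with zero classifiable patients are omitted with a warning.
    """
    if ce is None:
        ce = CeConfig()
    oop = [total_oop(record) for record in records]
    results: dict[str, CeResult] = {}
    for instrument, incomes in incomes_by_instrument.items():
        if len(incomes) != len(records):
            raise ValueError(
                f"{instrument}: {len(incomes)} incomes for "
                f"{len(records)} records")
        flags = [classify_catastrophic(o, income, ce)
                 for o, income in zip(oop, incomes)]
        classified = [f for f in flags if f is not None]
        if not classified:
            warnings.warn(
                f"instrument {instrument!r}: no classifiable patients; "
                "omitted from CE results")
            continue
        n = len(classified)
        k = sum(classified)
        ci_low, ci_high = proportion_confint(k, n, alpha=0.05,
                                             method="wilson")
        results[instrument] = CeResult(
            instrument=instrument, threshold_fraction=ce.threshold_fraction,
            n_classified=n, n_catastrophic=k, rate=k / n,
            ci_low=float(ci_low), ci_high=float(ci_high))
        log.info("CE %s @ %.0f%%: %d/%d = %.1f%% (95%% CI %.1f-%.1f)",
                 instrument, 100 * ce.threshold_fraction, k, n, 100 * k / n,
                 100 * ci_low, 100 * ci_high)
    return results
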