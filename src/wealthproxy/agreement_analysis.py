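"""Distribution summaries and non-parametric Bland-Altman agreement.

Income data from household surveys are heavily right-skewed, so classical
Bland-Altman 95% limits of agreement (mean difference +/- 1.96 SD) are only
shown when the differences pass a normality test.  The primary agreement
summary is non-parametric: the proportion of complete pairs whose absolute
difference lies within fixed monetary bands (default 25k/50k/100k INR).

Sign convention: difference = reported - estimated, so an instrument that
systematically over-estimates income produces negative differences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

DEFAULT_BANDS = (25_000.0, 50_000.0, 100_000.0)


@dataclass(frozen=True)
class DistributionSummary:
    """Summary metrics + exportable histogram/density data for one
    instrument's income distribution.

    Quartiles use linear interpolation between order statistics
    (numpy's default quantile rule).  The kernel density uses a Gaussian
    kernel with Scott's plug-in bandwidth, evaluated on a grid clipped at
    zero income.
    """

    n: int
    n_missing: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    hist_edges: np.ndarray
    hist_counts: np.ndarray
    density_x: np.ndarray
    density_y: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n": self.n, "n_missing": self.n_missing, "mean": self.mean,
            "sd": self.sd, "median": self.median, "q1": self.q1,
            "q3": self.q3,
        }


def summarize_distribution(values, bins: int | str = "fd",
                           density_points: int = 200) -> DistributionSummary:
    """Summarise one instrument's values (NaN/None = missing)."""
    arr = np.asarray(
        [np.nan if v is None else v for v in np.ravel(values)], dtype=float)
    observed = arr[~np.isnan(arr)]
    n_missing = int(arr.size - observed.size)
    if observed.size == 0:
        raise ValueError("summarize_distribution: all values missing")
    q1, median, q3 = np.percentile(observed, [25, 50, 75])
    sd = float(np.std(observed, ddof=1)) if observed.size > 1 else 0.0
    hist_counts, hist_edges = np.histogram(observed, bins=bins)
    if observed.size > 1 and np.ptp(observed) > 0:
        kde = stats.gaussian_kde(observed)  # Scott bandwidth
        lo = max(0.0, observed.min() - 2 * kde.factor * observed.std())
        hi = observed.max() + 2 * kde.factor * observed.std()
        density_x = np.linspace(lo, hi, density_points)
        density_y = kde(density_x)
        log.debug("KDE bandwidth factor %.4f (Scott)", kde.factor)
    else:
        density_x = np.asarray([])
        density_y = np.asarray([])
    return DistributionSummary(
        n=int(observed.size), n_missing=n_missing,
        mean=float(np.mean(observed)), sd=sd, median=float(median),
        q1=float(q1), q3=float(q3), hist_edges=hist_edges,
        hist_counts=hist_counts, density_x=density_x, density_y=density_y)


def bland_altman_points(reported, estimated) -> pd.DataFrame:
    """Per-patient (pair_mean, difference) for complete pairs only.

    difference = reported - estimated; pair_mean = (reported + estimated)/2.
    """
    rep = np.asarray(
        [np.nan if v is None else v for v in np.ravel(reported)], dtype=float)
    est = np.asarray(
        [np.nan if v is None else v for v in np.ravel(estimated)], dtype=float)
    if rep.shape != est.shape:
        raise ValueError("reported and estimated must align")
    complete = ~np.isnan(rep) & ~np.isnan(est)
    return pd.DataFrame({
        "pair_mean": (rep[complete] + est[complete]) / 2.0,
        "difference": rep[complete] - est[complete],
    })


@dataclass(frozen=True)
class BandedAgreement:
    """Proportion of complete pairs with |difference| within each band."""

    bands: tuple[float, ...]
    proportions: tuple[float, ...]
    n_pairs: int

    def as_dict(self) -> dict:
        return {"n_pairs": self.n_pairs,
                "bands": {f"{band:g}": prop
                          for band, prop in zip(self.bands, self.proportions)}}


def banded_agreement(points, bands: Sequence[float] = DEFAULT_BANDS
                     ) -> BandedAgreement:
    """Non-parametric agreement: for each band b, the proportion of pairs
    with |reported - estimated| <= b (boundary inclusive).

    ``points`` is the frame from :func:`bland_altman_points` or a plain
    sequence of differences.  Bands must be strictly increasing, positive.
    """
    bands = tuple(float(b) for b in bands)
    if not bands or any(b <= 0 for b in bands):
        raise ValueError("bands must be positive")
    if any(b2 <= b1 for b1, b2 in zip(bands, bands[1:])):
        raise ValueError(f"bands must be strictly increasing, got {bands}")
    if isinstance(points, pd.DataFrame):
        diffs = points["difference"].to_numpy(dtype=float)
    else:
        diffs = np.asarray(points, dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    if diffs.size == 0:
        raise ValueError("banded_agreement: no complete pairs")
    proportions = tuple(float(np.mean(np.abs(diffs) <= b)) for b in bands)
    return BandedAgreement(bands=bands, proportions=proportions,
                           n_pairs=int(diffs.size))


@dataclass(frozen=True)
class NormalityReport:
    """Normality diagnostics on the Bland-Altman differences.

    ``parametric_loa_permitted`` is False when the test rejects at
    alpha = 0.05 (or when diagnostics are unavailable): classical 95%
    limits of agreement are then suppressed and the banded proportions are
    the primary output.
    """

    n: int
    method: str
    statistic: float
    p_value: float
    parametric_loa_permitted: bool
    qq_theoretical: np.ndarray
    qq_observed: np.ndarray

    def as_dict(self) -> dict:
        return {"n": self.n, "method": self.method,
                "statistic": self.statistic, "p_value": self.p_value,
                "parametric_loa_permitted": self.parametric_loa_permitted}


def normality_diagnostics(differences, alpha: float = 0.05
                          ) -> NormalityReport:
    """Shapiro-Wilk (n <= 5000) or D'Agostino K^2 (larger n) on the
    differences, with Q-Q points for plotting."""
    diffs = np.asarray(
        [np.nan if v is None else v for v in np.ravel(differences)],
        dtype=float)
    diffs = diffs[~np.isnan(diffs)]
    n = int(diffs.size)
    if n < 3:
        warnings.warn("normality diagnostics need >= 3 differences; "
                      "parametric limits suppressed by policy")
        return NormalityReport(n=n, method="unavailable",
                               statistic=float("nan"), p_value=float("nan"),
                               parametric_loa_permitted=False,
                               qq_theoretical=np.asarray([]),
                               qq_observed=np.asarray([]))
    (qq_theoretical, qq_observed), _ = stats.probplot(diffs, dist="norm")
    if np.ptp(diffs) == 0:
        warnings.warn("constant differences: normality test degenerate; "
                      "parametric limits suppressed")
        return NormalityReport(n=n, method="degenerate",
                               statistic=float("nan"), p_value=float("nan"),
                               parametric_loa_permitted=False,
                               qq_theoretical=qq_theoretical,
                               qq_observed=qq_observed)
    if n <= 5000:
        method = "shapiro-wilk"
        statistic, p_value = stats.shapiro(diffs)
    else:
        method = "dagostino-k2"
        statistic, p_value = stats.normaltest(diffs)
    return NormalityReport(
        n=n, method=method, statistic=float(statistic),
        p_value=float(p_value),
        parametric_loa_permitted=bool(p_value >= alpha),
        qq_theoretical=qq_theoretical, qq_observed=qq_observed)
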