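"""End-to-end run orchestration, reporting and figure export.

``run_pipeline`` ties the stages together: load (or simulate) a cohort,
derive the three instrument incomes per patient, summarise each income
distribution, run the non-parametric Bland-Altman agreement of each
estimator against self-report, and compute catastrophic-expenditure rates
per instrument and threshold.  Every figure has a tidy-CSV twin and all
numbers in the run report are plain recomputations of module-level calls.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

from .agreement_analysis import (
    DEFAULT_BANDS,
    BandedAgreement,
    DistributionSummary,
    NormalityReport,
    banded_agreement,
    bland_altman_points,
    normality_diagnostics,
    summarize_distribution,
)
from .catastrophic_expenditure import CeConfig, ce_rates, total_oop
from .cohort_model import (
    AnalysisConfig,
    EconomicConfig,
    PatientRecord,
    load_config,
    read_cohort,
    write_results,
)
from .gapminder_estimator import (
    GapminderCatalogue,
    default_catalogue,
    gapminder_income,
    load_catalogue,
)
from .iwi_scoring import (
    IwiWeightTable,
    compute_iwi_score,
    load_weight_table,
    score_to_monthly_inr,
)
from .synthetic_cohort import generate_cohort

log = logging.getLogger(__name__)

#: instrument keys used throughout reports
INSTRUMENTS = ("self_reported", "iwi", "gapminder")


def derive_table(records: Sequence[PatientRecord],
                 econ: EconomicConfig,
                 weight_table: IwiWeightTable | None = None,
                 catalogue: GapminderCatalogue | None = None) -> pd.DataFrame:
    """Per-patient derived quantities: IWI score, the three monthly
    incomes (INR) and the OOP total.  Missing instruments stay NaN."""
    weight_table = (weight_table if weight_table is not None
                    else load_weight_table())
    catalogue = catalogue if catalogue is not None else default_catalogue()
    rows = []
    for record in records:
        score = compute_iwi_score(record.assets, weight_table)
        rows.append({
            "patient_id": record.patient_id,
            "self_reported": record.self_reported_monthly_income,
            "iwi_score": score,
            "iwi": (score_to_monthly_inr(score, econ)
                    if score is not None else None),
            "gapminder": gapminder_income(record.selection, catalogue, econ),
            "oop_total": total_oop(record),
        })
    frame = pd.DataFrame(rows)
    for column in ("self_reported", "iwi_score", "iwi", "gapminder",
                   "oop_total"):
        frame[column] = frame[column].astype(float)
    return frame


@dataclass
class RunReport:
    """Serializable end-of-run summary; every number is a stage output."""

    config_provenance: dict[str, str]
    n_records: int
    missingness: dict[str, int]
    distributions: dict[str, dict]
    agreement: dict[str, dict]
    normality: dict[str, dict]
    ce: dict[str, dict]
    manifest: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2,
                                   sort_keys=True) + "\n", encoding="utf-8")
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "RunReport":
        return cls(**json.loads(Path(path).read_text(encoding="utf-8")))


def _plot_distributions(summaries: Mapping[str, DistributionSummary],
                        derived: pd.DataFrame, outdir: Path) -> list[Path]:
    import matplotlib.pyplot as plt

    paths = []
    for instrument in INSTRUMENTS:
        if instrument not in summaries:
            continue
        summary = summaries[instrument]
        fig, ax = plt.subplots(figsize=(6, 4))
        values = derived[instrument].dropna()
        ax.hist(values, bins=summary.hist_edges, density=True, alpha=0.6,
                color="tab:blue")
        if summary.density_x.size:
            ax.plot(summary.density_x, summary.density_y, color="tab:red")
        ax.set_xlabel("monthly household income (INR)")
        ax.set_ylabel("density")
        ax.set_title(f"{instrument}: median {summary.median:,.0f} INR "
                     f"(IQR {summary.q1:,.0f}-{summary.q3:,.0f})")
        path = outdir / f"income_distribution_{instrument}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)

    fig, ax = plt.subplots(figsize=(6, 4))
    for instrument in INSTRUMENTS:
        if instrument in summaries and summaries[instrument].density_x.size:
            ax.plot(summaries[instrument].density_x,
                    summaries[instrument].density_y, label=instrument)
    ax.set_xlabel("monthly household income (INR)")
    ax.set_ylabel("density")
    ax.legend()
    path = outdir / "income_density_combined.png"
    fig.savefig(path, dpi=120, bbox_inches="tight")
    plt.close(fig)
    paths.append(path)
    return paths


def _plot_bland_altman(points_by_pair: Mapping[str, pd.DataFrame],
                       bands: Sequence[float], outdir: Path) -> list[Path]:
    import matplotlib.pyplot as plt

    paths = []
    for pair, points in points_by_pair.items():
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.scatter(points["pair_mean"], points["difference"], s=10,
                   alpha=0.6)
        ax.axhline(0.0, color="black")
        for band in bands:
            for sign in (1, -1):
                ax.axhline(sign * band, color="grey", linestyle=":")
        ax.set_xlabel("mean of the two incomes (INR)")
        ax.set_ylabel("reported - estimated (INR)")
        ax.set_title(f"Bland-Altman: self-reported vs {pair}")
        path = outdir / f"bland_altman_{pair}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def _plot_ce(ce_report: Mapping[str, Mapping[str, Any]],
             outdir: Path) -> list[Path]:
    import matplotlib.pyplot as plt

    paths = []
    for threshold_key, per_instrument in ce_report.items():
        instruments = [i for i in INSTRUMENTS if i in per_instrument]
        rates = [per_instrument[i]["rate"] for i in instruments]
        errs = np.clip(np.asarray(
            [[per_instrument[i]["rate"] - per_instrument[i]["ci_low"]
              for i in instruments],
             [per_instrument[i]["ci_high"] - per_instrument[i]["rate"]
              for i in instruments]]), 0.0, None)
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.bar(instruments, rates, yerr=errs, capsize=4,
               color=["tab:blue", "tab:orange", "tab:green"])
        ax.set_ylim(0, 1)
        ax.set_ylabel("catastrophic expenditure rate")
        ax.set_title(f"CE rate at {threshold_key} of annual income")
        path = outdir / f"ce_rates_{threshold_key.replace('%', 'pct')}.png"
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        paths.append(path)
    return paths


def run_pipeline(output_dir: str | Path,
                 cohort_path: str | Path | None = None,
                 config_path: str | Path | None = None,
                 simulate_n: int | None = None,
                 seed: int | None = None,
                 catalogue_path: str | Path | None = None,
                 weights_path: str | Path | None = None,
                 ce_thresholds: Sequence[float] | None = None,
                 bands: Sequence[float] = DEFAULT_BANDS,
                 make_plots: bool = True) -> RunReport:
    """Full analysis run.  Either ``cohort_path`` or simulation
    (``simulate_n``/config defaults) supplies the cohort; outputs (tidy
    CSVs, JSON report, optional figures) land in ``output_dir``."""
    outdir = Path(output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: list[Path] = []

    config: AnalysisConfig = load_config(config_path)
    econ = config.economic
    weight_table = load_weight_table(weights_path)
    catalogue = (load_catalogue(catalogue_path) if catalogue_path
                 else default_catalogue())

    if cohort_path is not None:
        records = read_cohort(cohort_path)
    else:
        gen = config.generator
        if simulate_n is not None:
            gen = dataclasses.replace(gen, n=simulate_n)
        if seed is not None:
            gen = dataclasses.replace(gen, seed=seed)
        records, truth = generate_cohort(gen, econ, weight_table, catalogue)
        manifest.append(write_results(records, outdir / "cohort.csv"))
        truth_path = outdir / "truth.csv"
        truth.to_csv(truth_path, index=False)
        manifest.append(truth_path)

    derived = derive_table(records, econ, weight_table, catalogue)

    # distribution summaries per instrument
    summaries: dict[str, DistributionSummary] = {}
    for instrument in INSTRUMENTS:
        values = derived[instrument]
        if values.notna().any():
            summaries[instrument] = summarize_distribution(values)
        else:
            log.warning("instrument %s entirely missing; analyses omitted",
                        instrument)

    # Bland-Altman agreement of each estimator against self-report
    points_by_pair: dict[str, pd.DataFrame] = {}
    agreement: dict[str, BandedAgreement] = {}
    normality: dict[str, NormalityReport] = {}
    for estimator in ("iwi", "gapminder"):
        if estimator not in summaries or "self_reported" not in summaries:
            continue
        points = bland_altman_points(derived["self_reported"],
                                     derived[estimator])
        if points.empty:
            log.warning("no complete pairs for self vs %s", estimator)
            continue
        points_by_pair[estimator] = points
        path = outdir / f"bland_altman_points_{estimator}.csv"
        points.to_csv(path, index=False)
        manifest.append(path)
        agreement[estimator] = banded_agreement(points, bands)
        normality[estimator] = normality_diagnostics(points["difference"])

    # CE rates per threshold
    thresholds = tuple(ce_thresholds) if ce_thresholds else (
        config.ce.threshold_fraction,)
    incomes_by_instrument = {
        instrument: derived[instrument].tolist()
        for instrument in INSTRUMENTS if instrument in summaries}
    ce_report: dict[str, dict[str, dict]] = {}
    for threshold in thresholds:
        ce_config = dataclasses.replace(config.ce,
                                        threshold_fraction=threshold)
        results = ce_rates(records, incomes_by_instrument, ce_config)
        ce_report[f"{100 * threshold:g}%"] = {
            instrument: result.as_dict()
            for instrument, result in results.items()}

    # derived CSV with CE flags at the first threshold
    first = ce_report[f"{100 * thresholds[0]:g}%"]
    flags = derived[["patient_id"]].copy()
    ce_config = dataclasses.replace(config.ce,
                                    threshold_fraction=thresholds[0])
    from .catastrophic_expenditure import classify_catastrophic
    for instrument in incomes_by_instrument:
        flags[f"ce_{instrument}"] = [
            "" if flag is None else str(int(flag))
            for flag in (classify_catastrophic(o, inc, ce_config)
                         for o, inc in zip(derived["oop_total"],
                                           derived[instrument]))]
    derived_out = derived.merge(flags, on="patient_id")
    manifest.append(write_results(records, outdir / "derived.csv",
                                  derived_out))

    agreement_path = outdir / "agreement.json"
    agreement_path.write_text(json.dumps(
        {pair: result.as_dict() for pair, result in agreement.items()},
        indent=2, sort_keys=True) + "\n", encoding="utf-8")
    manifest.append(agreement_path)
    ce_path = outdir / "ce_rates.json"
    ce_path.write_text(json.dumps(ce_report, indent=2, sort_keys=True) + "\n",
                       encoding="utf-8")
    manifest.append(ce_path)

    if make_plots:
        manifest += _plot_distributions(summaries, derived, outdir)
        manifest += _plot_bland_altman(points_by_pair, bands, outdir)
        manifest += _plot_ce(ce_report, outdir)

    report = RunReport(
        config_provenance=config.provenance,
        n_records=len(records),
        missingness={
            "self_reported": int(derived["self_reported"].isna().sum()),
            "iwi": int(derived["iwi"].isna().sum()),
            "gapminder": int(derived["gapminder"].isna().sum()),
            "oop": int(derived["oop_total"].isna().sum()),
        },
        distributions={k: v.as_dict() for k, v in summaries.items()},
        agreement={k: v.as_dict() for k, v in agreement.items()},
        normality={k: v.as_dict() for k, v in normality.items()},
        ce=ce_report,
        manifest=[str(p.relative_to(outdir)) for p in manifest],
    )
    report.to_json(outdir / "report.json")
    return report
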