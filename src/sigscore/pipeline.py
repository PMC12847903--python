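"""End-to-end retrospective analysis driver.

Chains scoring -> classification contrast -> SIG balance -> survival
correlation -> median-split survival -> volcano differential -> subtype
assignment on an abundance table plus optional clinical annotations, and
collects everything in an :class:`AnalysisReport` that can be written to a
directory of TSV/JSON files. Stages whose inputs are missing (no clinical
table, no survival columns, single group) are skipped with a logged
notice rather than failing the run.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .catalog import SigCatalog, default_catalog
from .cohort import (CohortRecord, ContrastResult, CorrelationResult,
                     MedianSplitResult, assign_subtypes, balance_histogram,
                     classification_contrast, median_split_survival,
                     sig_count_balance, subtype_frame, survival_correlation,
                     volcano_differential)
from .errors import (DegenerateSplitError, InsufficientDataError,
                     UndefinedStatisticError, ValidationError)
from .ingest import AbundanceTable, clr_transform
from .scoring import SigScoreResult, score_cohort, scores_frame

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class AnalysisParameters:
    """Shared knobs of the retrospective pipeline."""

    detection_threshold: float = 0.0
    pseudocount: float = 1e-5
    split_threshold: float | None = None   # None: cohort median of n_sig1
    retention_modest: float = 0.4
    retention_collapse: float = 0.15
    oral_min: float = 0.5
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class AnalysisReport:
    """All stage outputs of one pipeline run plus provenance."""

    scores: pd.DataFrame
    balance: pd.DataFrame
    balance_bins: pd.DataFrame
    provenance: dict
    contrast: ContrastResult | None = None
    correlation_sig1: CorrelationResult | None = None
    correlation_sig2: CorrelationResult | None = None
    median_split_os: MedianSplitResult | None = None
    median_split_pfs: MedianSplitResult | None = None
    volcano: pd.DataFrame | None = None
    subtypes: pd.DataFrame | None = None
    notices: list[str] = field(default_factory=list)

    def summary(self) -> dict:
        """JSON-ready numeric summary of every completed stage."""
        out: dict = {"provenance": self.provenance, "notices": self.notices}
        labels = self.scores["final_label"]
        out["n_samples"] = int(len(self.scores))
        out["final_label_fractions"] = (
            labels.value_counts(normalize=True).to_dict())
        if self.contrast is not None:
            out["contrast"] = {
                "table_2x3": self.contrast.table_2x3.to_dict(),
                "fisher_p": self.contrast.p_value,
                "odds_ratio": self.contrast.odds_ratio,
            }
        for name, corr in (("sig1", self.correlation_sig1),
                           ("sig2", self.correlation_sig2)):
            if corr is not None:
                out[f"survival_correlation_{name}"] = {
                    "rho": corr.rho, "p_value": corr.p_value, "n": corr.n}
        for name, ms in (("os", self.median_split_os),
                         ("pfs", self.median_split_pfs)):
            if ms is not None:
                out[f"median_split_{name}"] = {
                    "threshold": ms.threshold,
                    "logrank_statistic": ms.logrank_statistic,
                    "logrank_p": ms.logrank_p,
                    "median_high": ms.median_high,
                    "median_low": ms.median_low,
                    "n_high": ms.n_high, "n_low": ms.n_low}
        return out

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.scores.to_csv(out / "scores.tsv", sep="\t", index=False)
        self.balance.to_csv(out / "balance.tsv", sep="\t", index=False)
        self.balance_bins.to_csv(out / "balance_bins.tsv", sep="\t",
                                 index=False)
        if self.contrast is not None:
            self.contrast.table_2x3.to_csv(out / "contrast_2x3.tsv", sep="\t")
            self.contrast.table_2x2.to_csv(out / "contrast_2x2.tsv", sep="\t")
        if self.volcano is not None:
            self.volcano.to_csv(out / "volcano.tsv", sep="\t", index=False)
        if self.subtypes is not None:
            self.subtypes.to_csv(out / "subtypes.tsv", sep="\t", index=False)
        for name, ms in (("os", self.median_split_os),
                         ("pfs", self.median_split_pfs)):
            if ms is not None:
                ms.km_high.to_csv(out / f"km_{name}_high.tsv", sep="\t",
                                  index=False)
                ms.km_low.to_csv(out / f"km_{name}_low.tsv", sep="\t",
                                 index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(self.summary(), fh, indent=1, default=float)
            fh.write("\n")


def _check_alignment(table: AbundanceTable,
                     clinical: Sequence[CohortRecord]) -> None:
    table_ids = set(table.sample_ids)
    clin_ids = {r.sample_id for r in clinical}
    orphans_clin = sorted(clin_ids - table_ids)
    orphans_table = sorted(table_ids - clin_ids)
    if orphans_clin or orphans_table:
        raise ValidationError(
            "sample ids misaligned between abundance table and clinical "
            f"table; clinical-only: {orphans_clin[:10]}, "
            f"table-only: {orphans_table[:10]}")


def run_retrospective_analysis(
        table: AbundanceTable,
        clinical: Sequence[CohortRecord] | None = None,
        catalog: SigCatalog | None = None,
        params: AnalysisParameters | None = None) -> AnalysisReport:
    """Run the full retrospective workflow on one cohort.

    The clinical table supplies group membership (healthy/cancer) and the
    survival endpoints; without it only scoring and the SIG balance are
    produced. Identical inputs and parameters yield an identical report.
    """
    catalog = catalog or default_catalog()
    params = params or AnalysisParameters()
    if clinical:
        _check_alignment(table, clinical)

    notices: list[str] = []

    def notice(msg: str) -> None:
        logger.info(msg)
        notices.append(msg)

    results = score_cohort(table, catalog, params.detection_threshold)
    scores = scores_frame(results)
    balance = sig_count_balance(results)
    bins = balance_histogram(balance)

    provenance = {
        "tool": "sigscore",
        "version": __version__,
        "catalog_hash": catalog.content_hash(),
        "parameters": params.to_dict(),
        "n_samples": table.n_samples,
        "n_taxa": table.n_taxa,
    }
    report = AnalysisReport(scores=scores, balance=balance, balance_bins=bins,
                            provenance=provenance, notices=notices)

    if not clinical:
        notice("no clinical table: contrast and survival stages skipped")
        return report

    by_group: dict[str, list[SigScoreResult]] = {"healthy": [], "cancer": []}
    group_of = {r.sample_id: r.group for r in clinical}
    for res in results:
        by_group[group_of[res.sample_id]].append(res)

    if by_group["healthy"] and by_group["cancer"]:
        report.contrast = classification_contrast(
            by_group["healthy"], by_group["cancer"])
    else:
        notice("only one group present: classification contrast skipped")

    # survival analyses run on the cancer group (the published analysis);
    # fall back to the whole cohort when no cancer samples exist
    if by_group["cancer"]:
        survival_pool = by_group["cancer"]
        pool_clin = [r for r in clinical if r.group == "cancer"]
    else:
        survival_pool = list(results)
        pool_clin = list(clinical)
    has_os = any(r.os_months is not None for r in pool_clin)
    if has_os:
        for which in ("sig1", "sig2"):
            try:
                corr = survival_correlation(survival_pool, pool_clin, which)
            except (InsufficientDataError, UndefinedStatisticError) as exc:
                notice(f"survival correlation ({which}) skipped: {exc}")
                corr = None
            setattr(report, f"correlation_{which}", corr)
        for endpoint in ("os", "pfs"):
            try:
                ms = median_split_survival(
                    survival_pool, pool_clin, endpoint=endpoint,
                    threshold=params.split_threshold)
            except (InsufficientDataError, DegenerateSplitError,
                    UndefinedStatisticError) as exc:
                notice(f"median-split survival ({endpoint}) skipped: {exc}")
                ms = None
            setattr(report, f"median_split_{endpoint}", ms)
    else:
        notice("no survival times recorded: survival stages skipped")

    try:
        clr = clr_transform(table, params.pseudocount)
        report.volcano = volcano_differential(clr, survival_pool)
    except InsufficientDataError as exc:
        notice(f"volcano differential skipped: {exc}")

    subtypes = assign_subtypes(
        table, results, catalog, params.detection_threshold,
        retention_modest=params.retention_modest,
        retention_collapse=params.retention_collapse,
        oral_min=params.oral_min)
    report.subtypes = subtype_frame(subtypes)
    return report
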