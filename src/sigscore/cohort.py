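"""Retrospective cohort statistics on scored samples.

Covers the healthy-vs-cancer classification contrast (Fisher's exact
test), the SIG1/SIG2 balance histogram, Spearman correlation of SIG counts
with overall survival, Kaplan-Meier curves with a log-rank test after a
median split on the SIG1 count, rank-sum differential abundance between
SIG1-high and SIG1-low samples, and the Type 1 / Type 2 compositional
dysbiosis subtyping of dysbiotic samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.stats.contingency import odds_ratio as _odds_ratio
from statsmodels.stats.multitest import multipletests

from .catalog import (LABEL_GRAY, LABEL_SIG1, LABEL_SIG2, SigCatalog,
                      TaxonId, default_catalog)
from .errors import (DegenerateSplitError, InsufficientDataError,
                     UndefinedStatisticError, ValidationError)
from .ingest import AbundanceTable, ClrTable
from .scoring import SigScoreResult, presence_matrix

LABEL_ORDER = [LABEL_SIG1, LABEL_GRAY, LABEL_SIG2]

CLINICAL_COLUMNS = ["sample_id", "group", "cancer_type", "os_months",
                    "os_event", "pfs_months", "pfs_event"]


@dataclass(frozen=True)
class CohortRecord:
    """Per-sample clinical annotation (group membership and survival)."""

    sample_id: str
    group: str  # "healthy" | "cancer"
    cancer_type: str | None = None
    os_months: float | None = None
    os_event: bool | None = None
    pfs_months: float | None = None
    pfs_event: bool | None = None

    def __post_init__(self) -> None:
        if self.group not in ("healthy", "cancer"):
            raise ValidationError(f"unknown group {self.group!r}")
        for t, e, name in ((self.os_months, self.os_event, "os"),
                           (self.pfs_months, self.pfs_event, "pfs")):
            if t is not None:
                if t < 0:
                    raise ValidationError(f"{name}_months must be >= 0")
                if e is None:
                    raise ValidationError(
                        f"{name}_event required when {name}_months is present")


def read_clinical(path: str | Path) -> list[CohortRecord]:
    """Read a clinical CSV (columns: sample_id, group, cancer_type,
    os_months, os_event, pfs_months, pfs_event; missing values blank)."""
    df = pd.read_csv(path)
    records = []
    for _, row in df.iterrows():
        def _get(col, cast):
            v = row.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return cast(v)
        records.append(CohortRecord(
            sample_id=str(row["sample_id"]),
            group=str(row["group"]),
            cancer_type=_get("cancer_type", str),
            os_months=_get("os_months", float),
            os_event=_get("os_event", lambda v: bool(int(v))),
            pfs_months=_get("pfs_months", float),
            pfs_event=_get("pfs_event", lambda v: bool(int(v)))))
    return records


def write_clinical(records: Sequence[CohortRecord], path: str | Path) -> None:
    pd.DataFrame([{
        "sample_id": r.sample_id, "group": r.group,
        "cancer_type": r.cancer_type, "os_months": r.os_months,
        "os_event": None if r.os_event is None else int(r.os_event),
        "pfs_months": r.pfs_months,
        "pfs_event": None if r.pfs_event is None else int(r.pfs_event),
    } for r in records], columns=CLINICAL_COLUMNS).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# classification contrast

@dataclass(frozen=True)
class ContrastResult:
    """Healthy-vs-cancer label contingency analysis."""

    table_2x3: pd.DataFrame          # groups x (SIG1+, GRAY, SIG2+)
    table_2x2: pd.DataFrame          # groups x (SIG2+, not SIG2+)
    p_value: float                   # Fisher exact, two-sided, on the 2x2
    odds_ratio: float                # conditional MLE (Haldane fallback)
    proportions: pd.DataFrame        # per-group primary-label fractions
    p_value_2x3: float | None = None # Monte-Carlo exact test, if requested


def _label_counts(results: Sequence[SigScoreResult]) -> list[int]:
    labels = [r.primary_label for r in results]
    return [labels.count(lab) for lab in LABEL_ORDER]


def classification_contrast(healthy: Sequence[SigScoreResult],
                            cancer: Sequence[SigScoreResult],
                            exact_2x3: bool = False,
                            n_resamples: int = 20000,
                            seed: int = 0) -> ContrastResult:
    """Contrast primary label distributions between the two groups.

    The headline test is Fisher's exact two-sided test on the 2x2 collapse
    (SIG2+ vs not-SIG2+, i.e. eubiotic vs dysbiotic-or-gray). An optional
    Monte-Carlo exact test on the full 2x3 table is available via
    ``exact_2x3`` (probability-ordering p-value under fixed margins).
    """
    if not healthy or not cancer:
        raise InsufficientDataError("both groups must be non-empty")
    counts = pd.DataFrame([_label_counts(healthy), _label_counts(cancer)],
                          index=["healthy", "cancer"], columns=LABEL_ORDER)
    sig2 = counts[LABEL_SIG2]
    not_sig2 = counts[LABEL_SIG1] + counts[LABEL_GRAY]
    t22 = pd.DataFrame({"SIG2+": sig2, "not_SIG2+": not_sig2})
    arr = t22.to_numpy(dtype=int)
    _, p = stats.fisher_exact(arr, alternative="two-sided")
    if (arr == 0).any():
        a, b, c, d = (arr + 0.5).ravel()  # Haldane-Anscombe point estimate
        orat = (a * d) / (b * c)
    else:
        orat = float(_odds_ratio(arr, kind="conditional").statistic)
    props = counts.div(counts.sum(axis=1), axis=0)

    p23 = None
    if exact_2x3:
        p23 = _exact_rxc_pvalue(counts.to_numpy(dtype=int), n_resamples, seed)
    return ContrastResult(table_2x3=counts, table_2x2=t22, p_value=float(p),
                          odds_ratio=float(orat), proportions=props,
                          p_value_2x3=p23)


def _log_table_prob(table: np.ndarray) -> float:
    """Log-probability of an r x c table under the fixed-margins null."""
    r = table.sum(axis=1)
    c = table.sum(axis=0)
    n = table.sum()
    lg = math.lgamma
    return (sum(lg(x + 1) for x in r) + sum(lg(x + 1) for x in c)
            - lg(n + 1) - sum(lg(x + 1) for x in table.ravel()))


def _exact_rxc_pvalue(table: np.ndarray, n_resamples: int, seed: int) -> float:
    rng = np.random.default_rng(seed)
    dist = stats.random_table(table.sum(axis=1), table.sum(axis=0))
    samples = dist.rvs(n_resamples, random_state=rng).astype(int)
    obs = _log_table_prob(table)
    hits = sum(1 for s in samples if _log_table_prob(s) <= obs + 1e-12)
    return (hits + 1) / (n_resamples + 1)


# ---------------------------------------------------------------------------
# SIG balance

def sig_count_balance(results: Sequence[SigScoreResult]) -> pd.DataFrame:
    """Per-sample SIG balance, reported as n_sig1 - n_sig2 (positive means
    SIG1 dominance). Returns a frame with the difference per sample."""
    if not results:
        raise InsufficientDataError("empty cohort")
    return pd.DataFrame({
        "sample_id": [r.sample_id for r in results],
        "n_sig1": [r.n_sig1 for r in results],
        "n_sig2": [r.n_sig2 for r in results],
        "balance": [r.n_sig1 - r.n_sig2 for r in results],
    })


def balance_histogram(balance: pd.DataFrame) -> pd.DataFrame:
    """Integer-binned counts of the balance, mirror-histogram ready."""
    vals = balance["balance"].to_numpy()
    bins = np.arange(vals.min(), vals.max() + 1)
    counts = [(vals == b).sum() for b in bins]
    return pd.DataFrame({"balance": bins, "count": counts})


# ---------------------------------------------------------------------------
# survival

def _survival_frame(results: Sequence[SigScoreResult],
                    clinical: Sequence[CohortRecord],
                    endpoint: str = "os") -> pd.DataFrame:
    by_id = {r.sample_id: r for r in results}
    rows = []
    for rec in clinical:
        res = by_id.get(rec.sample_id)
        t = rec.os_months if endpoint == "os" else rec.pfs_months
        e = rec.os_event if endpoint == "os" else rec.pfs_event
        if res is None or t is None:
            continue
        rows.append({"sample_id": rec.sample_id, "n_sig1": res.n_sig1,
                     "n_sig2": res.n_sig2, "time": t, "event": bool(e)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float
    n: int


def survival_correlation(results: Sequence[SigScoreResult],
                         clinical: Sequence[CohortRecord],
                         which: str = "sig1",
                         events_only: bool = False) -> CorrelationResult:
    """Spearman correlation between a SIG count and overall survival time.

    By default all samples with a recorded follow-up time enter, regardless
    of censoring status (matching the published analysis); ``events_only``
    restricts to observed deaths, the statistically safer variant.
    """
    if which not in ("sig1", "sig2"):
        raise ValidationError("which must be 'sig1' or 'sig2'")
    df = _survival_frame(results, clinical, "os")
    if events_only and len(df):
        df = df[df["event"]]
    if len(df) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired observations, got {len(df)}")
    counts = df["n_sig1" if which == "sig1" else "n_sig2"].to_numpy()
    times = df["time"].to_numpy()
    if np.ptp(counts) == 0 or np.ptp(times) == 0:
        raise UndefinedStatisticError(
            "Spearman correlation undefined on constant input")
    rho, p = stats.spearmanr(counts, times)
    return CorrelationResult(rho=float(rho), p_value=float(p), n=len(df))


@dataclass(frozen=True)
class MedianSplitResult:
    """Kaplan-Meier comparison of high- vs low-SIG1 arms."""

    threshold: float
    endpoint: str
    n_high: int
    n_low: int
    events_high: int
    events_low: int
    km_high: pd.DataFrame     # columns: time, survival
    km_low: pd.DataFrame
    median_high: float        # months; inf when never reached
    median_low: float
    logrank_statistic: float
    logrank_p: float


def median_split_survival(results: Sequence[SigScoreResult],
                          clinical: Sequence[CohortRecord],
                          endpoint: str = "os",
                          threshold: float | None = None) -> MedianSplitResult:
    """Split the cohort at a SIG1-count threshold (default: cohort median)
    and compare survival with Kaplan-Meier curves and a log-rank test.

    The high arm is n_sig1 > threshold, the low arm n_sig1 <= threshold.
    """
    if endpoint not in ("os", "pfs"):
        raise ValidationError("endpoint must be 'os' or 'pfs'")
    df = _survival_frame(results, clinical, endpoint)
    if df.empty:
        raise InsufficientDataError("no samples with survival data")
    if threshold is None:
        threshold = float(np.median(df["n_sig1"]))
    high = df[df["n_sig1"] > threshold]
    low = df[df["n_sig1"] <= threshold]
    if high.empty or low.empty:
        raise DegenerateSplitError(
            f"threshold {threshold} leaves an empty arm "
            f"(high n = {len(high)}, low n = {len(low)})")
    if not df["event"].any():
        raise UndefinedStatisticError(
            "log-rank test undefined on a fully censored cohort")

    curves = {}
    medians = {}
    for name, arm in (("high", high), ("low", low)):
        kmf = KaplanMeierFitter()
        kmf.fit(arm["time"], event_observed=arm["event"])
        sf = kmf.survival_function_
        curves[name] = pd.DataFrame({"time": sf.index.to_numpy(),
                                     "survival": sf.iloc[:, 0].to_numpy()})
        medians[name] = float(kmf.median_survival_time_)
    lr = logrank_test(high["time"], low["time"],
                      event_observed_A=high["event"],
                      event_observed_B=low["event"])
    return MedianSplitResult(
        threshold=float(threshold), endpoint=endpoint,
        n_high=len(high), n_low=len(low),
        events_high=int(high["event"].sum()), events_low=int(low["event"].sum()),
        km_high=curves["high"], km_low=curves["low"],
        median_high=medians["high"], median_low=medians["low"],
        logrank_statistic=float(lr.test_statistic),
        logrank_p=float(lr.p_value))


# ---------------------------------------------------------------------------
# differential abundance

@dataclass(frozen=True)
class DifferentialResult:
    taxon: TaxonId
    effect: float      # CLR mean difference, high - low
    p_value: float
    q_value: float


def volcano_differential(clr: ClrTable, results: Sequence[SigScoreResult],
                         threshold: float | None = None) -> pd.DataFrame:
    """Taxon-wise differential CLR abundance between SIG1-high and SIG1-low
    samples (two-sided Wilcoxon rank-sum, BH-adjusted).

    The split is at the cohort median SIG1 count unless ``threshold`` is
    given; high = n_sig1 > threshold. Returns a frame with columns taxon,
    effect (CLR mean difference high - low), p_value, q_value.
    """
    by_id = {r.sample_id: r for r in results}
    ids = [s for s in clr.data.index if s in by_id]
    if not ids:
        raise InsufficientDataError("no scored samples in the CLR table")
    n1 = np.array([by_id[s].n_sig1 for s in ids])
    if threshold is None:
        threshold = float(np.median(n1))
    mask_high = n1 > threshold
    sub = clr.data.loc[ids]
    high = sub.loc[mask_high]
    low = sub.loc[~mask_high]
    if len(high) < 3 or len(low) < 3:
        raise InsufficientDataError(
            f"both groups need >= 3 samples (high n = {len(high)}, "
            f"low n = {len(low)})")

    effects, pvals = [], []
    for col in sub.columns:
        a = high[col].to_numpy(dtype=float)
        b = low[col].to_numpy(dtype=float)
        effects.append(float(a.mean() - b.mean()))
        if np.ptp(np.concatenate([a, b])) == 0:
            pvals.append(1.0)
        else:
            pvals.append(float(stats.mannwhitneyu(
                a, b, alternative="two-sided").pvalue))
    _, qvals, _, _ = multipletests(pvals, method="fdr_bh")
    return pd.DataFrame({
        "taxon": list(sub.columns),
        "effect": effects,
        "p_value": pvals,
        "q_value": qvals,
    })


# ---------------------------------------------------------------------------
# compositional dysbiosis subtypes

SUBTYPE_1 = "type1"
SUBTYPE_2 = "type2"
SUBTYPE_NONE = "unclassified"


@dataclass(frozen=True)
class DysbiosisSubtype:
    """Compositional dysbiosis subtype of a SIG1+ sample.

    Type 1: modest SIG2 loss with oral-species spillover. Type 2: near
    complete SIG2 collapse dominated by gut-resident SIG1 anaerobes.
    """

    sample_id: str
    subtype: str
    sig2_retention: float
    oral_fraction: float


def assign_subtype(result: SigScoreResult, detected: set[str],
                   catalog: SigCatalog | None = None,
                   retention_modest: float = 0.4,
                   retention_collapse: float = 0.15,
                   oral_min: float = 0.5) -> DysbiosisSubtype:
    """Assign a Type 1 / Type 2 compositional-dysbiosis subtype.

    ``detected`` is the set of detected catalog canonical names for the
    sample. ``sig2_retention`` = n_sig2 / |SIG2|; ``oral_fraction`` = share
    of detected SIG1 taxa belonging to the oral cluster. Type 1 requires a
    retention of at least ``retention_modest`` with oral fraction >=
    ``oral_min``; Type 2 requires retention below ``retention_collapse``
    with oral fraction < ``oral_min``. Everything else — including every
    non-dysbiotic sample — is unclassified.
    """
    catalog = catalog or default_catalog()
    retention = result.n_sig2 / catalog.n_sig2
    sig1_detected = [t for t in catalog.sig1 if t.canonical in detected]
    oral = {t.canonical for t in catalog.sig1_oral}
    oral_fraction = (sum(1 for t in sig1_detected if t.canonical in oral)
                     / max(1, len(sig1_detected)))
    if result.final_label != LABEL_SIG1:
        subtype = SUBTYPE_NONE
    elif retention < retention_collapse and oral_fraction < oral_min:
        subtype = SUBTYPE_2
    elif retention >= retention_modest and oral_fraction >= oral_min:
        subtype = SUBTYPE_1
    else:
        subtype = SUBTYPE_NONE
    return DysbiosisSubtype(sample_id=result.sample_id, subtype=subtype,
                            sig2_retention=retention,
                            oral_fraction=oral_fraction)


def assign_subtypes(table: AbundanceTable, results: Sequence[SigScoreResult],
                    catalog: SigCatalog | None = None,
                    detection_threshold: float = 0.0,
                    **cutoffs) -> list[DysbiosisSubtype]:
    """Vector version of :func:`assign_subtype` over a scored table."""
    catalog = catalog or default_catalog()
    presence = presence_matrix(table, catalog, detection_threshold)
    out = []
    for r in results:
        det = set(presence.columns[presence.loc[r.sample_id]])
        out.append(assign_subtype(r, det, catalog, **cutoffs))
    return out


def subtype_frame(subtypes: Sequence[DysbiosisSubtype]) -> pd.DataFrame:
    return pd.DataFrame([{
        "sample_id": s.sample_id, "subtype": s.subtype,
        "sig2_retention": s.sig2_retention, "oral_fraction": s.oral_fraction,
    } for s in subtypes])
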