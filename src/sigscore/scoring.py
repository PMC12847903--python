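"""Per-sample SIG scoring and the eubiotic/dysbiotic classification.

The score of a sample is

    S = 1/2 * (N_SIG2 / 45 - N_SIG1 / 37 + 1)

where N_SIG1 and N_SIG2 count the unique SIG1 / SIG2 catalog taxa detected
in the sample (denominators are the catalog group sizes). S lives in [0, 1]:
0.5 is the neutral point, low scores mean SIG1 dominance. Samples with
S <= 0.535 are called SIG1+ (dysbiotic), S >= 0.791 SIG2+ (eubiotic), and
the gray zone in between is resolved by *Akkermansia muciniphila*: samples
lacking it or carrying it above 4.799% are SIG1+, samples with normal
levels are SIG2+.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import (LABEL_GRAY, LABEL_SIG1, LABEL_SIG2, SigCatalog,
                      default_catalog)
from .errors import ValidationError
from .ingest import AbundanceTable

GRAY_NOT = "not_gray"
GRAY_AKK_ABSENT = "akk_absent"
GRAY_AKK_OVER = "akk_over"
GRAY_AKK_NORMAL = "akk_normal"

SCORE_COLUMNS = ["sample_id", "n_sig1", "n_sig2", "score", "primary_label",
                 "final_label", "gray_resolution", "akk_abundance"]


@dataclass(frozen=True)
class SigScoreResult:
    """Scoring outcome for one sample, including how a gray-zone call was
    resolved."""

    sample_id: str
    n_sig1: int
    n_sig2: int
    score: float
    primary_label: str
    final_label: str
    gray_resolution: str
    akk_abundance: float


def compute_sig_score(n_sig1: int, n_sig2: int,
                      sig1_total: int = 37, sig2_total: int = 45) -> float:
    """S = 1/2 (n_sig2/sig2_total - n_sig1/sig1_total + 1), in [0, 1]."""
    if not (0 <= n_sig1 <= sig1_total):
        raise ValidationError(
            f"n_sig1 must be in [0, {sig1_total}], got {n_sig1}")
    if not (0 <= n_sig2 <= sig2_total):
        raise ValidationError(
            f"n_sig2 must be in [0, {sig2_total}], got {n_sig2}")
    return 0.5 * (n_sig2 / sig2_total - n_sig1 / sig1_total + 1.0)


def classify_sample(score: float, akk_abundance: float, akk_detected: bool,
                    catalog: SigCatalog | None = None
                    ) -> tuple[str, str, str]:
    """Apply the two thresholds and the gray-zone Akkermansia trichotomy.

    Returns ``(primary_label, final_label, gray_resolution)``. Boundary
    handling is inclusive on the score thresholds (<= t_low, >= t_high) and
    strict on the overabundance cutoff (> akk_over_cutoff).
    """
    catalog = catalog or default_catalog()
    if not (0.0 <= score <= 1.0):
        raise ValidationError(f"score must lie in [0, 1], got {score}")
    if score <= catalog.t_low:
        return LABEL_SIG1, LABEL_SIG1, GRAY_NOT
    if score >= catalog.t_high:
        return LABEL_SIG2, LABEL_SIG2, GRAY_NOT
    if not akk_detected:
        return LABEL_GRAY, LABEL_SIG1, GRAY_AKK_ABSENT
    if akk_abundance > catalog.akk_over_cutoff:
        return LABEL_GRAY, LABEL_SIG1, GRAY_AKK_OVER
    return LABEL_GRAY, LABEL_SIG2, GRAY_AKK_NORMAL


def _column_map(table: AbundanceTable, catalog: SigCatalog) -> dict[str, str]:
    """Map catalog canonical name -> table column, matching by canonical
    name first and falling back to a shared SGB code."""
    by_canon = {t.canonical: t.canonical for t in table.taxa}
    by_sgb = {t.sgb: t.canonical for t in table.taxa if t.sgb}
    mapping: dict[str, str] = {}
    for taxon in (*catalog.sig1, *catalog.sig2, catalog.akkermansia):
        if taxon.canonical in by_canon:
            mapping[taxon.canonical] = by_canon[taxon.canonical]
        elif taxon.sgb and taxon.sgb in by_sgb:
            mapping[taxon.canonical] = by_sgb[taxon.sgb]
    return mapping


def presence_matrix(table: AbundanceTable, catalog: SigCatalog | None = None,
                    detection_threshold: float = 0.0) -> pd.DataFrame:
    """Boolean samples x catalog-taxa matrix of detection calls.

    A catalog taxon absent from the table counts as undetected everywhere.
    Columns are catalog canonical names, SIG1 first then SIG2.
    """
    catalog = catalog or default_catalog()
    if detection_threshold < 0:
        raise ValidationError("detection_threshold must be >= 0")
    mapping = _column_map(table, catalog)
    out = {}
    for taxon in (*catalog.sig1, *catalog.sig2):
        col = mapping.get(taxon.canonical)
        if col is None:
            out[taxon.canonical] = np.zeros(table.n_samples, dtype=bool)
        else:
            out[taxon.canonical] = (
                table.data[col].to_numpy(dtype=float) > detection_threshold)
    return pd.DataFrame(out, index=table.data.index)


def detect_presence(table: AbundanceTable, catalog: SigCatalog | None = None,
                    detection_threshold: float = 0.0) -> pd.DataFrame:
    """Per-sample (n_sig1, n_sig2, akk_abundance, akk_detected).

    A taxon is detected when its relative abundance strictly exceeds
    ``detection_threshold`` (default 0: any nonzero call counts).
    """
    catalog = catalog or default_catalog()
    presence = presence_matrix(table, catalog, detection_threshold)
    sig1_cols = [t.canonical for t in catalog.sig1]
    sig2_cols = [t.canonical for t in catalog.sig2]
    mapping = _column_map(table, catalog)
    akk_col = mapping.get(catalog.akkermansia.canonical)
    if akk_col is None:
        akk = np.zeros(table.n_samples)
    else:
        akk = table.data[akk_col].to_numpy(dtype=float)
    return pd.DataFrame({
        "n_sig1": presence[sig1_cols].sum(axis=1).astype(int),
        "n_sig2": presence[sig2_cols].sum(axis=1).astype(int),
        "akk_abundance": akk,
        "akk_detected": akk > detection_threshold,
    }, index=table.data.index)


def score_cohort(table: AbundanceTable, catalog: SigCatalog | None = None,
                 detection_threshold: float = 0.0) -> list[SigScoreResult]:
    """Score every sample of a table, in table order."""
    catalog = catalog or default_catalog()
    counts = detect_presence(table, catalog, detection_threshold)
    results = []
    for sample_id, row in counts.iterrows():
        n1, n2 = int(row["n_sig1"]), int(row["n_sig2"])
        score = compute_sig_score(n1, n2, catalog.n_sig1, catalog.n_sig2)
        primary, final, gray = classify_sample(
            score, float(row["akk_abundance"]), bool(row["akk_detected"]),
            catalog)
        results.append(SigScoreResult(
            sample_id=str(sample_id), n_sig1=n1, n_sig2=n2, score=score,
            primary_label=primary, final_label=final, gray_resolution=gray,
            akk_abundance=float(row["akk_abundance"])))
    return results


def scores_frame(results: list[SigScoreResult]) -> pd.DataFrame:
    """Tabulate scoring results (one row per sample, TSV-ready)."""
    return pd.DataFrame([{
        "sample_id": r.sample_id, "n_sig1": r.n_sig1, "n_sig2": r.n_sig2,
        "score": r.score, "primary_label": r.primary_label,
        "final_label": r.final_label, "gray_resolution": r.gray_resolution,
        "akk_abundance": r.akk_abundance,
    } for r in results], columns=SCORE_COLUMNS)
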