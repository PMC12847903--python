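"""Reading species-level relative-abundance tables and the CLR transform.

The on-disk format is the MetaPhlAn-style merged abundance TSV: first column
``clade_name`` holding full clade strings (or plain species names), one
column per sample, values in percent. ``#``-prefixed header lines are
tolerated. In memory the table is samples x taxa, so every downstream
operation works on a plain :class:`pandas.DataFrame`.

Relative abundances are compositional: per-sample vectors carry only
relative information, so association and differential analyses operate on
centered log-ratio (CLR) transformed values, computed here with a small
additive pseudocount for zeros.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.composition import clr as _skbio_clr

from .catalog import TaxonId, normalize_taxon_name
from .errors import ValidationError

logger = logging.getLogger(__name__)

#: slack allowed on the per-sample species-level sum above 100%
SUM_TOLERANCE = 0.5


@dataclass(frozen=True)
class AbundanceTable:
    """Samples x taxa relative abundances in percent.

    ``data`` is indexed by sample id with canonical taxon names as columns;
    ``taxa`` carries the full :class:`TaxonId` records in column order.
    """

    data: pd.DataFrame
    taxa: tuple[TaxonId, ...]

    def __post_init__(self) -> None:
        values = self.data.to_numpy(dtype=float)
        if (values < 0).any():
            raise ValidationError("abundances must be non-negative")
        if (values > 100).any():
            raise ValidationError("relative abundances cannot exceed 100%")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].tolist()
            raise ValidationError(f"duplicate sample ids: {dupes}")
        canon = [t.canonical for t in self.taxa]
        if list(self.data.columns) != canon:
            raise ValidationError("taxa metadata out of sync with columns")
        if len(set(canon)) != len(canon):
            dupes = sorted({c for c in canon if canon.count(c) > 1})
            raise ValidationError(f"duplicate canonical taxa: {dupes}")
        sums = values.sum(axis=1)
        bad = self.data.index[sums > 100 + SUM_TOLERANCE].tolist()
        if bad:
            raise ValidationError(
                f"per-sample species-level abundances exceed 100%: {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_samples(self) -> int:
        return len(self.data)

    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    def taxon(self, canonical: str) -> TaxonId:
        for t in self.taxa:
            if t.canonical == canonical:
                return t
        raise KeyError(canonical)

    def subset_taxa(self, canonicals: list[str]) -> "AbundanceTable":
        keep = [t for t in self.taxa if t.canonical in set(canonicals)]
        return AbundanceTable(self.data[[t.canonical for t in keep]], tuple(keep))


@dataclass(frozen=True)
class ClrTable:
    """CLR-transformed abundances on the same axes as the source table;
    rows sum to zero."""

    data: pd.DataFrame
    taxa: tuple[TaxonId, ...]
    pseudocount: float

    def __post_init__(self) -> None:
        sums = self.data.to_numpy(dtype=float).sum(axis=1)
        if np.abs(sums).max(initial=0.0) > 1e-9 * max(1, self.data.shape[1]):
            raise ValidationError("CLR rows must sum to zero")


def table_from_arrays(sample_ids, taxa: list[TaxonId], values) -> AbundanceTable:
    """Build a validated table from raw pieces (values: samples x taxa)."""
    df = pd.DataFrame(np.asarray(values, dtype=float),
                      index=list(sample_ids),
                      columns=[t.canonical for t in taxa])
    return AbundanceTable(df, tuple(taxa))


def _is_species_row(clade: str, rank: str) -> bool:
    last = clade.split("|")[-1].strip()
    if rank == "species":
        return last.lower().startswith("s__")
    if rank == "sgb":
        return last.lower().startswith("t__sgb")
    raise ValidationError(f"unknown rank filter: {rank!r}")


def read_abundance_table(path: str | Path, rank: str = "species") -> AbundanceTable:
    """Read a MetaPhlAn-style merged TSV, keeping rows at the requested rank.

    ``rank`` is ``"species"`` (``s__`` clades, the default) or ``"sgb"``
    (``t__SGB`` clades). Files with plain species names and no rank prefixes
    are accepted as-is. Tables whose per-sample sums look like proportions
    (all close to or below 1) are rescaled to percent with a warning.
    """
    lines = Path(path).read_text().splitlines()
    header = None
    body: list[str] = []
    for line in lines:
        if not line.strip():
            continue
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped.lower().startswith("clade_name") and "\t" in stripped:
                header = stripped
            continue
        if header is None and not body:
            header = line
            continue
        body.append(line)
    if header is None or not body:
        raise ValidationError(f"{path}: no parseable table content")

    columns = header.split("\t")
    sample_ids = [c.strip() for c in columns[1:]]
    if not sample_ids:
        raise ValidationError(f"{path}: table has no sample columns")

    clades, rows = [], []
    for line in body:
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise ValidationError(
                f"{path}: row with {len(parts)} fields, expected {len(columns)}")
        clades.append(parts[0].strip())
        try:
            rows.append([float(v) for v in parts[1:]])
        except ValueError as exc:
            raise ValidationError(f"{path}: non-numeric abundance value") from exc

    has_prefixes = any("__" in c for c in clades)
    if has_prefixes:
        keep = [i for i, c in enumerate(clades) if _is_species_row(c, rank)]
    else:
        keep = list(range(len(clades)))  # plain species names: take all rows
    if not keep:
        raise ValidationError(f"{path}: no rows at rank {rank!r}")

    taxa = [normalize_taxon_name(clades[i]) for i in keep]
    canon = [t.canonical for t in taxa]
    if len(set(canon)) != len(canon):
        dupes = sorted({c for c in canon if canon.count(c) > 1})
        raise ValidationError(f"{path}: duplicate canonical taxa: {dupes}")

    values = np.asarray([rows[i] for i in keep], dtype=float).T  # samples x taxa
    if (values < 0).any():
        raise ValidationError(f"{path}: negative abundance values")

    sums = values.sum(axis=1)
    if len(sums) and sums.max() <= 1.005 and sums.max() > 0.2:
        logger.warning("%s: per-sample sums look like proportions; rescaling "
                       "to percent", path)
        values = values * 100.0

    return table_from_arrays(sample_ids, taxa, values)


def write_abundance_table(table: AbundanceTable, path: str | Path) -> None:
    """Write back in the same TSV dialect (lossless round trip at this rank)."""
    with open(path, "w") as fh:
        fh.write("clade_name\t" + "\t".join(table.sample_ids) + "\n")
        values = table.data.to_numpy(dtype=float)
        for j, taxon in enumerate(table.taxa):
            vals = "\t".join(repr(float(v)) for v in values[:, j])
            fh.write(f"{taxon.raw_name}\t{vals}\n")


def clr_transform(table: AbundanceTable, pseudocount: float = 1e-5) -> ClrTable:
    """Centered log-ratio transform with an additive pseudocount (percent).

    value(i, j) = ln((x_ij + pc) / g_i) with g_i the geometric mean of the
    pseudocounted sample row; rows sum to zero by construction.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be strictly positive")
    shifted = table.data.to_numpy(dtype=float) + pseudocount
    values = _skbio_clr(shifted)
    df = pd.DataFrame(values, index=table.data.index, columns=table.data.columns)
    return ClrTable(df, table.taxa, pseudocount)
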