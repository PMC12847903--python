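"""Taxon co-abundance networks and Ward-linkage partitioning.

Edges are Spearman rank correlations between CLR-transformed abundances,
kept when their Benjamini-Hochberg adjusted two-sided p-value passes the
significance level; positive edges read as co-occurrence, negative as
co-exclusion. The same correlation matrix drives agglomerative clustering
with Ward's minimum-variance linkage on the distance d = 1 - rho, cut
either to a fixed number of clusters (default 10 major clusters) or at a
dendrogram height.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr
from statsmodels.stats.multitest import multipletests

from .catalog import TaxonId
from .errors import InsufficientDataError, ValidationError
from .ingest import AbundanceTable, clr_transform

SIGN_POSITIVE = "positive"
SIGN_NEGATIVE = "negative"


@dataclass(frozen=True)
class Edge:
    taxon_a: str
    taxon_b: str
    weight: float
    sign: str
    q_value: float


@dataclass
class CoAbundanceNetwork:
    """Signed taxon-taxon association network with optional clustering.

    ``correlation`` keeps the full Spearman matrix over nodes so the Ward
    partition can reuse it; ``linkage_matrix`` and ``cluster_of`` are filled
    by :func:`ward_partition`.
    """

    nodes: tuple[TaxonId, ...]
    edges: tuple[Edge, ...]
    correlation: pd.DataFrame
    cluster_of: dict[str, int] | None = None
    linkage_matrix: np.ndarray | None = None
    alpha: float = 0.05
    min_prevalence: float = 0.1

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for t in self.nodes:
            attrs = {"sgb": t.sgb or ""}
            if self.cluster_of is not None:
                attrs["cluster"] = int(self.cluster_of[t.canonical])
            g.add_node(t.canonical, **attrs)
        for e in self.edges:
            g.add_edge(e.taxon_a, e.taxon_b, weight=e.weight, sign=e.sign,
                       q_value=e.q_value)
        return g

    def edge_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "taxon_a": e.taxon_a, "taxon_b": e.taxon_b, "weight": e.weight,
            "sign": e.sign, "q_value": e.q_value} for e in self.edges],
            columns=["taxon_a", "taxon_b", "weight", "sign", "q_value"])

    def cluster_frame(self) -> pd.DataFrame:
        if self.cluster_of is None:
            raise ValidationError("network has not been partitioned yet")
        return pd.DataFrame(
            [{"taxon": t.canonical, "cluster": self.cluster_of[t.canonical]}
             for t in self.nodes], columns=["taxon", "cluster"])


def _clr_spearman(table: AbundanceTable, taxa: list[TaxonId],
                  pseudocount: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    sub = table.subset_taxa([t.canonical for t in taxa])
    clr = clr_transform(sub, pseudocount)
    values = clr.data.to_numpy(dtype=float)
    rho, pval = spearmanr(values, axis=0)
    if values.shape[1] == 2:  # scipy collapses the 2-column case to scalars
        rho = np.array([[1.0, float(rho)], [float(rho), 1.0]])
        pval = np.array([[0.0, float(pval)], [float(pval), 0.0]])
    else:
        rho = np.asarray(rho, dtype=float)
        pval = np.asarray(pval, dtype=float)
    cols = clr.data.columns
    return (pd.DataFrame(rho, index=cols, columns=cols),
            pd.DataFrame(pval, index=cols, columns=cols))


def build_coabundance_network(table: AbundanceTable,
                              min_prevalence: float = 0.1,
                              alpha: float = 0.05,
                              pseudocount: float = 1e-5) -> CoAbundanceNetwork:
    """Reconstruct the signed co-abundance network of a cohort.

    Taxa present (abundance > 0) in at least ``min_prevalence`` of samples
    become nodes; all node pairs are tested with Spearman correlation of CLR
    abundances and edges are kept when the BH-adjusted two-sided p-value is
    <= ``alpha``. Edge weight is the correlation itself.
    """
    if table.n_samples < 10:
        raise InsufficientDataError(
            f"co-abundance network needs >= 10 samples, got {table.n_samples}")
    if not (0.0 <= min_prevalence <= 1.0):
        raise ValidationError("min_prevalence must lie in [0, 1]")
    if not (0.0 < alpha <= 1.0):
        raise ValidationError("alpha must lie in (0, 1]")

    prevalence = (table.data.to_numpy(dtype=float) > 0).mean(axis=0)
    nodes = tuple(t for t, p in zip(table.taxa, prevalence)
                  if p >= min_prevalence)
    if len(nodes) < 2:
        raise InsufficientDataError(
            "fewer than 2 taxa pass the prevalence filter")

    rho, pval = _clr_spearman(table, list(nodes), pseudocount)
    names = list(rho.columns)
    iu = np.triu_indices(len(names), k=1)
    pvec = pval.to_numpy()[iu]
    pvec = np.where(np.isnan(pvec), 1.0, pvec)
    _, qvec, _, _ = multipletests(pvec, method="fdr_bh")

    edges = []
    for (i, j), q in zip(zip(*iu), qvec):
        if q <= alpha:
            w = float(rho.iloc[i, j])
            if w == 0.0 or np.isnan(w):
                continue
            edges.append(Edge(names[i], names[j], w,
                              SIGN_POSITIVE if w > 0 else SIGN_NEGATIVE,
                              float(q)))
    return CoAbundanceNetwork(nodes=nodes, edges=tuple(edges),
                              correlation=rho, alpha=alpha,
                              min_prevalence=min_prevalence)


def ward_partition(source: AbundanceTable | CoAbundanceNetwork,
                   n_clusters: int | None = None,
                   height_cut: float | None = None,
                   pseudocount: float = 1e-5
                   ) -> tuple[dict[str, int], np.ndarray]:
    """Partition taxa by Ward-linkage hierarchical clustering.

    The distance is d = 1 - rho on the Spearman correlation of CLR
    abundances (computed from the table, or reused from an existing
    network). Exactly one of ``n_clusters`` / ``height_cut`` selects the
    cut. Returns ``(cluster_of, linkage_matrix)`` and, when called on a
    network, stores both on it.
    """
    if (n_clusters is None) == (height_cut is None):
        raise ValidationError(
            "supply exactly one of n_clusters and height_cut")

    if isinstance(source, CoAbundanceNetwork):
        rho = source.correlation
        names = list(rho.columns)
    else:
        if source.n_taxa < 2:
            raise InsufficientDataError("clustering needs >= 2 taxa")
        rho, _ = _clr_spearman(source, list(source.taxa), pseudocount)
        names = list(rho.columns)

    if n_clusters is not None and n_clusters > len(names):
        raise ValidationError(
            f"n_clusters = {n_clusters} exceeds the {len(names)} nodes")

    dist = 1.0 - rho.to_numpy(dtype=float)
    dist = np.clip(dist, 0.0, None)
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    z = linkage(squareform(dist, checks=False), method="ward")

    if n_clusters is not None:
        labels = fcluster(z, t=n_clusters, criterion="maxclust")
    else:
        labels = fcluster(z, t=height_cut, criterion="distance")
    cluster_of = {name: int(c) for name, c in zip(names, labels)}

    if isinstance(source, CoAbundanceNetwork):
        source.cluster_of = cluster_of
        source.linkage_matrix = z
    return cluster_of, z


def write_edge_list(network: CoAbundanceNetwork, path: str | Path) -> None:
    network.edge_frame().to_csv(path, sep="\t", index=False)


def write_clusters(network: CoAbundanceNetwork, path: str | Path) -> None:
    network.cluster_frame().to_csv(path, sep="\t", index=False)


def write_graphml(network: CoAbundanceNetwork, path: str | Path) -> None:
    nx.write_graphml(network.to_networkx(), path)
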