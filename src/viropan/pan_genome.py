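"""De novo gene-family clustering from all-vs-all similarity hits.

The pan-genome route is independent of any reference ortholog database:
admit edges between proteins whose best hit passes identity (>= 20%) and
E-value (< 1e-5) thresholds, cluster the resulting weighted graph with
Markov clustering (MCL), derive a genomes x clusters presence/absence
matrix, and turn it into pairwise gene-content distances (Jaccard by
default) ready for neighbor joining.

MCL is implemented directly: the column-stochastic transition matrix with
self-loops is alternately squared (expansion) and entry-wise powered and
renormalized (inflation) until the iteration stabilizes; clusters are the
connected components of the attractor's support. The computation runs per
connected component of the input graph, which is exact (components never
mix) and keeps the dense matrix algebra small.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import HitRecord
from .phylo import DistanceMatrix

__all__ = [
    "ClusterSet",
    "build_similarity_graph",
    "mcl_cluster",
    "content_from_clusters",
    "content_distance",
]

logger = logging.getLogger(__name__)


@dataclass
class ClusterSet:
    """A partition of the protein set into clusters (singletons allowed)."""

    clusters: Dict[str, List[str]]
    converged: bool = True

    def __post_init__(self) -> None:
        members = [m for ms in self.clusters.values() for m in ms]
        if len(members) != len(set(members)):
            raise ValueError("clusters overlap: some protein appears twice")

    @property
    def n_proteins(self) -> int:
        return sum(len(m) for m in self.clusters.values())

    def membership(self) -> Dict[str, str]:
        return {m: cid for cid, ms in self.clusters.items() for m in ms}


def build_similarity_graph(
    hits: Iterable[HitRecord],
    min_identity: float = 20.0,
    evalue_max: float = 1e-5,
    proteins: Optional[Iterable[str]] = None,
) -> nx.Graph:
    """Weighted undirected similarity graph.

    An edge (i, j) is admitted iff some hit i->j (either direction) has
    percent identity >= ``min_identity`` and E-value strictly below
    ``evalue_max``; its weight is the maximum admitted bit score over both
    directions. Self hits are dropped. ``proteins`` adds isolated nodes
    for sequences with no admissible hit so they survive as singleton
    families.
    """
    g = nx.Graph(min_identity=min_identity, evalue_max=evalue_max)
    if proteins is not None:
        g.add_nodes_from(proteins)
    for h in hits:
        if h.query_id == h.subject_id:
            continue
        if h.pct_identity < min_identity or h.evalue >= evalue_max:
            continue
        u, v = h.query_id, h.subject_id
        if g.has_edge(u, v):
            g[u][v]["weight"] = max(g[u][v]["weight"], h.bit_score)
        else:
            g.add_edge(u, v, weight=h.bit_score)
    return g


def _mcl_component(
    sub: nx.Graph, inflation: float, max_iter: int, tol: float
) -> "tuple[List[List[str]], bool]":
    order = sorted(sub.nodes)
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n))
    for u, v, data in sub.edges(data=True):
        w = float(data.get("weight", 1.0))
        a[idx[u], idx[v]] = a[idx[v], idx[u]] = w
    # self-loop regularization: weight of the strongest incident edge
    row_max = a.max(axis=1)
    np.fill_diagonal(a, np.where(row_max > 0, row_max, 1.0))
    m = a / a.sum(axis=0, keepdims=True)

    converged = False
    for _ in range(max_iter):
        m2 = m @ m
        m2 = np.power(m2, inflation)
        m2[m2 < 1e-12] = 0.0
        col = m2.sum(axis=0, keepdims=True)
        col[col == 0] = 1.0
        m2 /= col
        delta = np.abs(m2 - m).max()
        m = m2
        if delta < tol:
            converged = True
            break
    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(m > 1e-6)
    support.add_edges_from(zip(rows, cols))
    comps = [sorted(order[i] for i in comp) for comp in nx.connected_components(support)]
    return comps, converged


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> ClusterSet:
    """Markov clustering of a similarity graph.

    Deterministic (node order within each component is sorted, so the
    result is invariant to node relabeling) and exact per connected
    component. If any component fails to stabilize within ``max_iter``
    iterations its best-effort clusters are kept and the result's
    ``converged`` flag is False.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty similarity graph")
    if inflation <= 1.0:
        raise ValueError("inflation must be > 1")
    all_clusters: List[List[str]] = []
    all_converged = True
    for comp in nx.connected_components(graph):
        if len(comp) == 1:
            all_clusters.append([next(iter(comp))])
            continue
        comps, converged = _mcl_component(
            graph.subgraph(comp), inflation, max_iter, tol
        )
        all_clusters.extend(comps)
        all_converged &= converged
    if not all_converged:
        warnings.warn("MCL did not stabilize within max_iter; clusters are best-effort")
    all_clusters.sort(key=lambda ms: ms[0])
    width = max(5, len(str(len(all_clusters))))
    clusters = {
        f"C{i + 1:0{width}d}": members for i, members in enumerate(all_clusters)
    }
    logger.info(
        "MCL: %d proteins -> %d clusters (%d singletons)",
        graph.number_of_nodes(),
        len(clusters),
        sum(1 for ms in clusters.values() if len(ms) == 1),
    )
    return ClusterSet(clusters=clusters, converged=all_converged)


def content_from_clusters(
    clusters: ClusterSet,
    protein_genome: Mapping[str, str],
    genomes: Optional[Sequence[str]] = None,
    mode: str = "presence",
) -> pd.DataFrame:
    """Genomes x clusters content matrix from a cluster set.

    ``presence``: 1 iff the cluster has >= 1 member from the genome;
    ``count``: number of members. Genomes defaults to the sorted set seen
    among the proteins.
    """
    if mode not in ("presence", "count"):
        raise ValueError("mode must be 'presence' or 'count'")
    if genomes is None:
        genomes = sorted({protein_genome[m] for ms in clusters.clusters.values() for m in ms})
    matrix = pd.DataFrame(
        0, index=list(genomes), columns=sorted(clusters.clusters), dtype=int
    )
    for cid, members in clusters.clusters.items():
        for m in members:
            g = protein_genome[m]
            if mode == "presence":
                matrix.at[g, cid] = 1
            else:
                matrix.at[g, cid] += 1
    matrix.index.name = "taxon"
    return matrix


def content_distance(matrix: pd.DataFrame, metric: str = "jaccard") -> DistanceMatrix:
    """Pairwise gene-content distances between genomes.

    ``jaccard``: 1 - |shared families| / |families in either| (bounded in
    [0, 1]). ``shared``: -ln(|shared| / min(|A|, |B|)), the classic
    gene-content distance; a zero intersection is capped with a 0.5
    pseudo-count so the matrix stays finite. A genome with no families at
    all gets distance 1 (jaccard) to every other genome, with a warning.
    """
    if metric not in ("jaccard", "shared"):
        raise ValueError("metric must be 'jaccard' or 'shared'")
    present = matrix.to_numpy() >= 1
    labels = [str(t) for t in matrix.index]
    sizes = present.sum(axis=1)
    empty = [labels[i] for i in np.nonzero(sizes == 0)[0]]
    if empty:
        warnings.warn(f"genomes with zero families: {empty}; distance set to maximum")
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            inter = int((present[i] & present[j]).sum())
            if metric == "jaccard":
                union = int((present[i] | present[j]).sum())
                dij = 1.0 if union == 0 else 1.0 - inter / union
            else:
                denom = min(sizes[i], sizes[j])
                if denom == 0:
                    dij = -np.log(0.5 / max(1, sizes.max()))
                else:
                    dij = -np.log(max(inter, 0.5) / denom)
            d[i, j] = d[j, i] = dij
    return DistanceMatrix(labels=tuple(labels), values=d)
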