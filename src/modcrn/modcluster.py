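"""Combined-module analysis: unification, GTOM clustering, profiles, hubs.

The two organ-specific regulatory modules are unified into a combined
module.  Its nodes are partitioned by hierarchical clustering of the
generalized topological overlap measure (GTOM) dissimilarity: for order
m = 1 the overlap of nodes i and j is

    t_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 - a_ij)

with a the adjacency indicator, l_ij the number of shared neighbours and k
the degrees; for m >= 2 the adjacency is first replaced by the m-step
reachability indicator (Yip-Horvath generalization).  Dissimilarity is
d = 1 - t.

Each cluster gets a representative per-sample expression profile (the
median over member proteins) and hub proteins are ranked by unnormalized
shortest-path betweenness centrality.  Clusters can be annotated against a
gene-set collection by one-sided Fisher tests with Benjamini-Hochberg
correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from scipy import stats
from sklearn.metrics import silhouette_score
from statsmodels.stats.multitest import multipletests

from .degcall import DEGResult
from .modisco import RegulatoryModule

logger = logging.getLogger(__name__)

__all__ = [
    "CombinedModule",
    "ClusterPartition",
    "ClusterExpression",
    "combine_modules",
    "gtom_dissimilarity",
    "cluster_proteins",
    "cluster_expression_profile",
    "betweenness_ranking",
    "cluster_geneset_enrichment",
]


@dataclass(frozen=True)
class CombinedModule:
    """Union of organ-specific regulatory modules.

    ``membership`` maps each node to the organ it came from, or ``"both"``
    for nodes shared by two or more modules.  ``log2fc`` optionally carries
    per-node per-organ fold changes for display.
    """

    nodes: frozenset[str]
    edges: frozenset[tuple[str, str]]
    membership: dict[str, str]
    log2fc: dict[str, dict[str, float]] = field(default_factory=dict)

    @property
    def n_shared(self) -> int:
        return sum(1 for v in self.membership.values() if v == "both")

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(sorted(self.nodes))
        g.add_edges_from(sorted(self.edges))
        return g


@dataclass(frozen=True)
class ClusterPartition:
    """Disjoint, covering partition of module nodes into dense integer IDs from 1."""

    clusters: dict[int, frozenset[str]]
    provenance: dict = field(default_factory=dict)

    def labels(self) -> dict[str, int]:
        return {n: cid for cid, members in self.clusters.items() for n in members}

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


@dataclass(frozen=True)
class ClusterExpression:
    """Median per-cluster per-sample profiles, raw and z-scaled."""

    profile: pd.DataFrame      # clusters x samples
    scaled: pd.DataFrame       # rows mean 0, sd 1 (where sd > 0)


def combine_modules(
    modules: list[RegulatoryModule],
    deg_results: dict[str, DEGResult] | None = None,
) -> CombinedModule:
    """Unify organ-specific modules into the combined module.

    Commutative and idempotent: node and edge sets are plain unions, and a
    node occurring in modules from two or more distinct organs is flagged
    ``"both"``.  If ``deg_results`` is given, per-node per-organ log2 fold
    changes are attached for display.
    """
    if not modules:
        raise ValueError("need at least one module to combine")
    nodes: set[str] = set()
    edges: set[tuple[str, str]] = set()
    origin: dict[str, set[str]] = {}
    for mod in modules:
        nodes |= mod.nodes
        edges |= mod.edges
        for n in mod.nodes:
            origin.setdefault(n, set()).add(mod.organ)
    membership = {
        n: ("both" if len(orgs) > 1 else next(iter(orgs))) for n, orgs in origin.items()
    }
    log2fc: dict[str, dict[str, float]] = {}
    if deg_results:
        for organ, res in deg_results.items():
            lfc = res.table["log2fc"]
            for n in nodes:
                if n in lfc.index:
                    log2fc.setdefault(n, {})[organ] = float(lfc[n])
    return CombinedModule(frozenset(nodes), frozenset(edges), membership, log2fc)


def gtom_dissimilarity(
    nodes: list[str] | frozenset[str],
    edges: set[tuple[str, str]] | frozenset[tuple[str, str]],
    m: int = 1,
) -> pd.DataFrame:
    """GTOM dissimilarity matrix of an unweighted graph.

    Returns a symmetric DataFrame in [0, 1] with zero diagonal, indexed by
    sorted node ID.  ``m`` is the neighbourhood order: 1 gives the plain
    topological overlap; m >= 2 replaces adjacency with the indicator of
    reachability within m steps before applying the same formula.
    """
    if m < 1:
        raise ValueError("GTOM order m must be >= 1")
    order = sorted(nodes)
    if len(order) < 2:
        raise ValueError("GTOM needs at least 2 nodes")
    idx = {n: i for i, n in enumerate(order)}
    n = len(order)
    a = np.zeros((n, n), dtype=float)
    for u, v in edges:
        a[idx[u], idx[v]] = 1.0
        a[idx[v], idx[u]] = 1.0
    if m > 1:
        reach = a.copy()
        power = a.copy()
        for _ in range(m - 1):
            power = power @ a
            reach += power
        a = (reach > 0).astype(float)
        np.fill_diagonal(a, 0.0)

    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    t = (shared + a) / denom
    np.fill_diagonal(t, 1.0)
    t = np.clip(t, 0.0, 1.0)
    d = 1.0 - t
    return pd.DataFrame(d, index=order, columns=order)


def cluster_proteins(
    dissimilarity: pd.DataFrame,
    k: int | None = None,
    cut_height: float | None = None,
    linkage: str = "average",
) -> ClusterPartition:
    """Agglomerative clustering of the GTOM dissimilarity.

    Cut by ``k`` (number of clusters) or ``cut_height``; when neither is
    given, k is chosen by maximizing the mean silhouette width over
    k in [2, min(30, n//3)] (smallest k on ties) — a deterministic default
    for studies that do not fix the cut.  Cluster IDs are dense integers
    from 1, assigned by each cluster's lexicographically smallest member.
    """
    nodes = list(dissimilarity.index)
    n = len(nodes)
    if k is not None and k > n:
        raise ValueError(f"k={k} exceeds number of nodes {n}")
    d = dissimilarity.to_numpy(dtype=float).copy()
    np.fill_diagonal(d, 0.0)
    z = hierarchy.linkage(squareform(d, checks=False), method=linkage)

    if k is None and cut_height is None:
        kmax = min(30, n // 3)
        if kmax < 2:
            k = min(2, n)
        else:
            best_k, best_s = None, -np.inf
            for kk in range(2, kmax + 1):
                labels = hierarchy.fcluster(z, t=kk, criterion="maxclust")
                if len(np.unique(labels)) < 2:
                    continue
                s = silhouette_score(d, labels, metric="precomputed")
                if s > best_s + 1e-12:
                    best_k, best_s = kk, s
            k = best_k if best_k is not None else min(2, n)
        logger.info("cluster_proteins: silhouette selected k=%d", k)

    if cut_height is not None and k is None:
        labels = hierarchy.fcluster(z, t=cut_height, criterion="distance")
        provenance_cut = {"cut_height": cut_height}
    else:
        labels = hierarchy.fcluster(z, t=k, criterion="maxclust")
        provenance_cut = {"k": int(k)}

    raw: dict[int, set[str]] = {}
    for node, lab in zip(nodes, labels):
        raw.setdefault(int(lab), set()).add(node)
    # dense IDs from 1, ordered by smallest member for determinism
    ordered = sorted(raw.values(), key=min)
    clusters = {i + 1: frozenset(members) for i, members in enumerate(ordered)}
    return ClusterPartition(
        clusters=clusters,
        provenance={"linkage": linkage, "gtom": "precomputed", **provenance_cut},
    )


def cluster_expression_profile(
    partition: ClusterPartition,
    expr: pd.DataFrame,
    meta: pd.DataFrame | None = None,
) -> ClusterExpression:
    """Median expression profile per cluster, plus a per-cluster z-scaled copy.

    Members absent from the expression matrix are dropped with a warning; a
    cluster with no measured member is an error.  Scaling is across samples
    (rows end up mean 0, sd 1 whenever the profile is non-constant; sd uses
    n-1 in the denominator).
    """
    measured = set(expr.index)
    rows = {}
    for cid in sorted(partition.clusters):
        members = sorted(partition.clusters[cid])
        present = [g for g in members if g in measured]
        absent = len(members) - len(present)
        if not present:
            raise ValueError(f"cluster {cid} has no members in the expression matrix")
        if absent:
            warnings.warn(f"cluster {cid}: {absent} member(s) not in expression matrix dropped")
        rows[cid] = expr.loc[present].median(axis=0)
    profile = pd.DataFrame(rows).T
    profile.index.name = "cluster"

    centered = profile.sub(profile.mean(axis=1), axis=0)
    sd = profile.std(axis=1, ddof=1)
    scaled = centered.div(sd.where(sd > 0, 1.0), axis=0)
    return ClusterExpression(profile=profile, scaled=scaled)


def betweenness_ranking(
    nodes: frozenset[str] | list[str],
    edges: set[tuple[str, str]] | frozenset[tuple[str, str]],
    top_n: int = 5,
) -> pd.DataFrame:
    """Rank proteins by unnormalized shortest-path betweenness centrality.

    Equal-length shortest paths split their contribution evenly.  The full
    table is returned sorted descending with lexicographic tie-break; the
    ``rank`` column makes the top-``top_n`` hubs explicit.
    """
    node_list = sorted(nodes)
    if not node_list:
        raise ValueError("graph is empty")
    g = nx.Graph()
    g.add_nodes_from(node_list)
    g.add_edges_from(sorted(edges))
    bc = nx.betweenness_centrality(g, normalized=False)
    table = pd.DataFrame(
        sorted(((n, v) for n, v in bc.items()), key=lambda t: (-t[1], t[0])),
        columns=["protein", "betweenness"],
    )
    table["rank"] = np.arange(1, len(table) + 1)
    table["is_hub"] = table["rank"] <= top_n
    return table


def cluster_geneset_enrichment(
    partition: ClusterPartition,
    genesets: dict[str, set[str]],
    background: set[str] | frozenset[str],
) -> pd.DataFrame:
    """Fisher enrichment of every (cluster, gene set) pair with BH correction.

    One-sided (greater) hypergeometric test on the background universe,
    which must contain all cluster members; Benjamini-Hochberg adjustment
    is applied across all tests in the table.
    """
    bg = set(background)
    all_members = set().union(*partition.clusters.values())
    if not all_members <= bg:
        raise ValueError("background must contain all cluster members")
    for name, members in genesets.items():
        if not members:
            raise ValueError(f"gene set {name!r} is empty")
    N = len(bg)
    rows = []
    for cid in sorted(partition.clusters):
        cluster = partition.clusters[cid] & bg
        for name in sorted(genesets):
            gset = genesets[name] & bg
            overlap = len(cluster & gset)
            p = float(stats.hypergeom.sf(overlap - 1, N, len(gset), len(cluster)))
            rows.append((cid, name, overlap, p))
    table = pd.DataFrame(rows, columns=["cluster", "gene_set", "overlap", "p"])
    table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1] if len(table) else []
    return table
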