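"""Clustering ESTs from a precomputed hybrid distance matrix.

The primary procedure is DBSCAN implemented directly from the two-function
pseudo-code (DBSCAN + expandCluster): scan ESTs in dataset order, grow a
cluster from every unvisited EST whose eps-neighborhood (self excluded)
holds at least ``min_points`` neighbors, and label everything unreachable
as a singleton (-1).  Single-linkage hierarchical clustering with a flat
distance cut is provided as the alternative method; at matching radius the
two give near-equivalent partitions on EST data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .distance import DistanceMatrix

__all__ = [
    "DBSCANParams",
    "ClusteringResult",
    "dbscan",
    "hierarchical",
    "cluster_summary",
]


@dataclass(frozen=True)
class DBSCANParams:
    """Neighborhood radius ``eps`` (in hybrid-distance units, optimal range
    0.1 ± 0.05) and the minimum neighbor count ``min_points`` for a point to
    seed or extend a cluster (default 2, the weakest density requirement
    that still separates clusters from singletons)."""

    eps: float = 0.1
    min_points: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.eps <= 1.0):
            raise ValueError("eps must lie in (0, 1]")
        if self.min_points < 1:
            raise ValueError("min_points must be >= 1")


@dataclass
class ClusteringResult:
    """Per-EST integer cluster labels; -1 marks a singleton (noise).

    Cluster ids are consecutive positive integers in order of creation,
    which for the deterministic scan order means order of first appearance
    in the dataset.
    """

    labels: Dict[str, int]

    @property
    def n_clusters(self) -> int:
        return len({c for c in self.labels.values() if c >= 1})

    def as_array(self) -> np.ndarray:
        return np.array(list(self.labels.values()), dtype=int)

    def clusters(self) -> Dict[int, List[str]]:
        """Cluster id → member ids (singletons under -1)."""
        out: Dict[int, List[str]] = {}
        for rid, c in self.labels.items():
            out.setdefault(c, []).append(rid)
        return out


def _check_matrix(m: DistanceMatrix) -> np.ndarray:
    v = np.asarray(m.values, dtype=float)
    if (v < 0).any() or (v > 1).any():
        raise ValueError(
            "distance matrix entries outside [0, 1]; cluster on a "
            "normalized/hybrid matrix, not raw d2"
        )
    return v


def dbscan(m: DistanceMatrix, params: DBSCANParams = DBSCANParams()) -> ClusteringResult:
    """Density-based clustering of a hybrid distance matrix.

    A point's neighborhood is every *other* point at distance <= eps. The
    scan visits ESTs in matrix (= dataset) order: an unvisited EST with
    fewer than ``min_points`` neighbors is provisionally labeled -1;
    otherwise it opens the next cluster id and the cluster is expanded
    breadth-first, merging the neighborhoods of core neighbors and adopting
    any not-yet-clustered point (including earlier noise) into the current
    cluster. Deterministic for a fixed input order.
    """
    v = _check_matrix(m)
    n = m.n
    eps, min_pts = params.eps, params.min_points
    neighbor_mask = (v <= eps) & ~np.eye(n, dtype=bool)
    labels = np.zeros(n, dtype=int)  # 0 = unclassified
    visited = np.zeros(n, dtype=bool)
    cid = 0
    for i in range(n):
        if visited[i]:
            continue
        visited[i] = True
        seeds = list(np.flatnonzero(neighbor_mask[i]))
        if len(seeds) < min_pts:
            labels[i] = -1
            continue
        cid += 1
        labels[i] = cid
        _expand_cluster(seeds, cid, labels, visited, neighbor_mask, min_pts)
    return ClusteringResult(labels=dict(zip(m.ids, labels.tolist())))


def _expand_cluster(
    seeds: List[int],
    cid: int,
    labels: np.ndarray,
    visited: np.ndarray,
    neighbor_mask: np.ndarray,
    min_pts: int,
) -> None:
    in_seeds = set(seeds)
    pos = 0
    while pos < len(seeds):
        j = seeds[pos]
        pos += 1
        if not visited[j]:
            visited[j] = True
            nbrs = np.flatnonzero(neighbor_mask[j])
            if len(nbrs) >= min_pts:  # j is itself a core point: merge gN* into gN
                for q in nbrs.tolist():
                    if q not in in_seeds:
                        in_seeds.add(q)
                        seeds.append(q)
        if labels[j] <= 0:  # unclassified or provisional noise
            labels[j] = cid


def hierarchical(m: DistanceMatrix, cut: float = 0.1) -> ClusteringResult:
    """Single-linkage agglomerative clustering with a flat cut.

    Clusters are the dendrogram leaves grouped at merge distance <= cut —
    equivalently the connected components of the graph with an edge wherever
    distance <= cut. Resulting size-1 clusters are reported as -1 to match
    the DBSCAN noise convention; multi-member clusters are renumbered
    consecutively by order of first appearance in the dataset.
    """
    v = _check_matrix(m)
    n = m.n
    if n < 2:
        return ClusteringResult(labels={rid: -1 for rid in m.ids})
    z = linkage(squareform(v, checks=False), method="single")
    flat = fcluster(z, t=cut, criterion="distance")
    sizes = np.bincount(flat)
    labels = np.full(n, -1, dtype=int)
    renumber: Dict[int, int] = {}
    for i in range(n):
        f = flat[i]
        if sizes[f] < 2:
            continue
        if f not in renumber:
            renumber[f] = len(renumber) + 1
        labels[i] = renumber[f]
    return ClusteringResult(labels=dict(zip(m.ids, labels.tolist())))


def cluster_summary(r: ClusteringResult) -> Dict[str, int]:
    """Counts used in reporting: number of clusters, largest/smallest
    cluster size, and how many ESTs are singletons."""
    groups = r.clusters()
    singletons = len(groups.get(-1, []))
    sizes = [len(v) for c, v in groups.items() if c >= 1]
    return {
        "n_clusters": len(sizes),
        "largest": max(sizes) if sizes else 0,
        "smallest": min(sizes) if sizes else 0,
        "singletons": singletons,
    }
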