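"""Brute-force reference implementations used only by the tests.

Each oracle recomputes a quantity by direct enumeration, independently of
the code paths it is checking: the windowed d² by recounting every window
from scratch, DBSCAN by repeated set expansion of density-reachability,
single-linkage flat cuts as graph connected components, and the Jaccard
index by enumerating all unordered pairs.
"""

from __future__ import annotations

from collections import Counter
from typing import Dict, List, Mapping, Sequence, Set, Tuple

import numpy as np

ACGT = set("ACGT")


# ---------------------------------------------------------------------------
# windowed d2


def naive_window_counters(seq: str, k: int, window: int) -> List[Counter]:
    """One Counter per window start, recounted from scratch (stride 1).

    A sequence shorter than the window is its own single window; words with
    characters outside {A,C,G,T} are skipped.
    """
    L = len(seq)
    w = min(window, L)
    counters = []
    for s in range(L - w + 1):
        win = seq[s : s + w]
        counters.append(
            Counter(
                win[i : i + k]
                for i in range(len(win) - k + 1)
                if set(win[i : i + k]) <= ACGT
            )
        )
    return counters


def naive_min_d2(p: str, q: str, k: int, window: int) -> int:
    """Minimum over all window pairs of Σ_w (c_p(w) − c_q(w))²."""
    cps = naive_window_counters(p, k, window)
    cqs = naive_window_counters(q, k, window)
    vocab = sorted({w for c in cps for w in c} | {w for c in cqs for w in c})
    idx = {w: i for i, w in enumerate(vocab)}
    a = np.zeros((len(cps), max(len(vocab), 1)), dtype=np.int64)
    b = np.zeros((len(cqs), max(len(vocab), 1)), dtype=np.int64)
    for r, c in enumerate(cps):
        for w, n in c.items():
            a[r, idx[w]] = n
    for r, c in enumerate(cqs):
        for w, n in c.items():
            b[r, idx[w]] = n
    best = None
    for r in range(a.shape[0]):
        d = ((a[r] - b) ** 2).sum(axis=1).min()
        best = d if best is None else min(best, d)
    return int(best)


# ---------------------------------------------------------------------------
# DBSCAN by repeated set expansion


def dbscan_oracle(dist: np.ndarray, eps: float, min_points: int) -> List[int]:
    """Density-reachability closure computed declaratively.

    Core points: at least ``min_points`` other points within eps. Clusters:
    transitive closure of core-core adjacency grown by repeated set
    expansion; numbered by the scan position of their first core point.
    Border points join the lowest-numbered adjacent cluster; the rest is
    noise (-1).
    """
    n = len(dist)
    nbrs: List[Set[int]] = [
        {j for j in range(n) if j != i and dist[i, j] <= eps} for i in range(n)
    ]
    core = {i for i in range(n) if len(nbrs[i]) >= min_points}
    comps: List[Set[int]] = []
    unassigned = set(core)
    while unassigned:
        comp = {min(unassigned)}
        while True:
            grow = {j for i in comp for j in nbrs[i] if j in core} - comp
            if not grow:
                break
            comp |= grow
        comps.append(comp)
        unassigned -= comp
    comps.sort(key=min)
    labels = [-1] * n
    for cid, comp in enumerate(comps, 1):
        for i in comp:
            labels[i] = cid
    for i in range(n):
        if i in core:
            continue
        adj = [cid for cid, comp in enumerate(comps, 1) if nbrs[i] & comp]
        if adj:
            labels[i] = min(adj)
    return labels


def partition_sets(labels: Sequence[int], ids: Sequence = None):
    """(noise ids, set of clusters-as-frozensets) for label-free comparison."""
    ids = list(range(len(labels))) if ids is None else list(ids)
    groups: Dict[int, Set] = {}
    noise = set()
    for i, lab in zip(ids, labels):
        if lab == -1:
            noise.add(i)
        else:
            groups.setdefault(lab, set()).add(i)
    return noise, {frozenset(g) for g in groups.values()}


# ---------------------------------------------------------------------------
# single linkage flat cut = connected components


def connected_components_labels(dist: np.ndarray, cut: float) -> List[int]:
    """Components of the graph with an edge wherever distance <= cut;
    size-1 components reported as -1, the rest numbered by first member."""
    n = len(dist)
    seen = [False] * n
    labels = [-1] * n
    cid = 0
    for i in range(n):
        if seen[i]:
            continue
        comp = {i}
        frontier = {i}
        while frontier:
            nxt = {
                j
                for f in frontier
                for j in range(n)
                if j not in comp and dist[f, j] <= cut
            }
            comp |= nxt
            frontier = nxt
        for j in comp:
            seen[j] = True
        if len(comp) > 1:
            cid += 1
            for j in comp:
                labels[j] = cid
    return labels


# ---------------------------------------------------------------------------
# Jaccard by pair enumeration


def jaccard_oracle(
    pred: Mapping[str, int], truth: Mapping[str, object]
) -> Tuple[float, int, int, int]:
    """Enumerate every unordered id pair; -1 predictions never co-cluster."""
    ids = sorted(pred)
    a = b = c = 0
    for x in range(len(ids)):
        for y in range(x + 1, len(ids)):
            i, j = ids[x], ids[y]
            same_pred = pred[i] == pred[j] and pred[i] != -1
            same_truth = truth[i] == truth[j]
            if same_pred and same_truth:
                a += 1
            elif same_pred:
                b += 1
            elif same_truth:
                c += 1
    denom = a + b + c
    return (1.0 if denom == 0 else a / denom), a, b, c


# ---------------------------------------------------------------------------
# sequence helpers


def random_dna(rng: np.random.Generator, length: int, n_frac: float = 0.0) -> str:
    bases = rng.choice(list("ACGT"), size=length)
    if n_frac > 0:
        mask = rng.random(length) < n_frac
        bases[mask] = "N"
    return "".join(bases)


def random_distance_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    """Random symmetric zero-diagonal matrix in [0,1] with planted block
    structure half the time, so DBSCAN tests see both regimes."""
    if rng.random() < 0.5:
        v = rng.random((n, n))
    else:
        centers = rng.integers(0, max(n // 8, 1) + 1, size=n)
        v = np.abs(centers[:, None] - centers[None, :]) * rng.uniform(0.1, 0.3)
        v = v + rng.uniform(0, 0.15, size=(n, n))
        v = np.clip(v, 0, 1)
    v = (v + v.T) / 2
    np.fill_diagonal(v, 0.0)
    return v
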