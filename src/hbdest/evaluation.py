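"""External cluster validation and parameter sweeps.

Clustering accuracy is scored with the pair-counting Jaccard index against
a reference partition (in real studies: alignment-derived gene
assignments; here also the simulator's truth labels).  The sweep harness
re-weights precomputed local/global matrices across the named weight
combinations and a grid of DBSCAN radii, which is exact because the hybrid
distance is linear in its two components.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .cluster import ClusteringResult, DBSCANParams, dbscan, hierarchical
from .distance import (
    WEIGHT_COMBOS,
    DistanceMatrix,
    HybridParams,
    combine,
    d2_matrix,
    gred_matrix,
    minmax_normalize,
)
from .io import ESTDataset

__all__ = ["JaccardComponents", "jaccard_index", "sweep"]


@dataclass(frozen=True)
class JaccardComponents:
    """Pair counts behind the index.

    a: EST pairs co-clustered in both the clustering C and the reference
       partition P_d; b: co-clustered in C only; c: co-clustered in P_d only.
    """

    a: int
    b: int
    c: int


def _pairs(sizes: Iterable[int]) -> int:
    return sum(s * (s - 1) // 2 for s in sizes)


def jaccard_index(
    pred: Union[ClusteringResult, Mapping[str, int]],
    truth: Mapping[str, object],
) -> Tuple[float, JaccardComponents]:
    """Jaccard index a / (a + b + c) over all unordered EST pairs.

    Every EST labeled -1 in the prediction is treated as its own singleton
    cluster, so two noise ESTs never count as co-clustered. The index is 1
    when both sides induce the same partition; the degenerate case
    a + b + c = 0 (all singletons on both sides) is defined as 1.
    """
    pred_labels = pred.labels if isinstance(pred, ClusteringResult) else dict(pred)
    missing = set(pred_labels) ^ set(truth)
    if missing:
        raise ValueError(
            "prediction and truth cover different ids; mismatched: "
            + ", ".join(sorted(missing)[:10])
        )
    ids = list(pred_labels)
    # -1 expands to a unique singleton label per EST
    p = [
        ("c", lab) if lab != -1 else ("s", i)
        for i, lab in enumerate(pred_labels[r] for r in ids)
    ]
    t = [truth[r] for r in ids]
    cont: Dict[Tuple[object, object], int] = {}
    psizes: Dict[object, int] = {}
    tsizes: Dict[object, int] = {}
    for pi, ti in zip(p, t):
        cont[(pi, ti)] = cont.get((pi, ti), 0) + 1
        psizes[pi] = psizes.get(pi, 0) + 1
        tsizes[ti] = tsizes.get(ti, 0) + 1
    a = _pairs(cont.values())
    b = _pairs(psizes.values()) - a
    c = _pairs(tsizes.values()) - a
    comp = JaccardComponents(a=a, b=b, c=c)
    denom = a + b + c
    return (1.0 if denom == 0 else a / denom), comp


def sweep(
    ds: ESTDataset,
    truth: Mapping[str, object],
    combos: Sequence[str] = tuple(WEIGHT_COMBOS),
    eps_grid: Sequence[float] = (0.05, 0.10, 0.15, 0.20, 0.25, 0.30),
    method: str = "dbscan",
    params: HybridParams = HybridParams(),
    min_points: int = 2,
    rc: bool = False,
) -> pd.DataFrame:
    """Clustering accuracy across weight combinations × neighborhood radii.

    The raw d² and gred matrices are computed once; each named combination
    (CB1..CB6 style, or explicit "A:B" strings) re-weights them — exact by
    linearity of the hybrid combination. Returns a long-format table with
    columns combo, weight_local, weight_global, eps, jaccard, n_clusters.
    """
    if method not in ("dbscan", "hier"):
        raise ValueError("method must be 'dbscan' or 'hier'")
    nd2 = minmax_normalize(d2_matrix(ds, params, rc=rc))
    gred = gred_matrix(ds, params.k)
    rows: List[Dict[str, object]] = []
    for combo in combos:
        if combo.upper() in WEIGHT_COMBOS:
            a, b = WEIGHT_COMBOS[combo.upper()]
        else:
            try:
                a, b = (float(x) for x in combo.split(":"))
            except ValueError:
                raise ValueError(
                    f"combo {combo!r} is neither a named combination nor 'A:B'"
                ) from None
        hp = params.with_weights(a, b)
        hybrid = combine(nd2, gred, hp)
        for eps in eps_grid:
            if method == "dbscan":
                res = dbscan(hybrid, DBSCANParams(eps=eps, min_points=min_points))
            else:
                res = hierarchical(hybrid, cut=eps)
            j, _ = jaccard_index(res, truth)
            rows.append(
                {
                    "combo": combo,
                    "weight_local": a,
                    "weight_global": b,
                    "eps": eps,
                    "jaccard": j,
                    "n_clusters": res.n_clusters,
                }
            )
    return pd.DataFrame(rows)
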