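"""The hybrid alignment-free EST distance hbd_EST.

Two ESTs from the same gene family can share a near-identical exon-length
block while the rest of their sequences diverge.  A windowed word-count
distance (the classic d², the *local* feature) sees only the best-matching
subsequence pair and therefore co-clusters such ESTs; a whole-sequence
word-frequency divergence (the *global* feature) sees the divergent
remainder.  The hybrid distance is their convex combination

    hbd(P, Q) = A * d2''(P, Q) + B * gred(P, Q),      A + B = 1,

where d2'' is the min–max-normalized windowed d² and gred is a bounded
relative-entropy distance between whole-sequence k-mer frequency vectors.
Values lie in [0, 1]; 0 means two identical ESTs.

Local feature (windowed d²)
    d²(p, q) = Σ_i (c_p(w_{k,i}) − c_q(w_{k,i}))²  over all 4^k words, for
    window-length subsequences p ⊂ P, q ⊂ Q; the distance between P and Q is
    the minimum over every window pair (stride 1).  A sequence shorter than
    the window contributes its whole length as the single window.

Global feature (gred)
    Base-2 Jensen–Shannon divergence between the k-mer frequency vectors of
    the full sequences: symmetric, in [0, 1], 0 iff the frequency vectors
    are equal and 1 iff their word supports are disjoint.

Defaults follow the comparative-study settings of the established windowed
d² tools: word size k = 6, window 100 bases, weights A = 0.9 / B = 0.1.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy.spatial.distance import jensenshannon

from .io import ESTDataset, ESTRecord

__all__ = [
    "HybridParams",
    "DistanceMatrix",
    "WEIGHT_COMBOS",
    "count_words",
    "word_freqs",
    "d2_distance",
    "gred_distance",
    "d2_matrix",
    "gred_matrix",
    "minmax_normalize",
    "combine",
    "hybrid_matrix",
    "reverse_complement",
]

# Named local/global weight combinations used in the comparative sweeps:
# the local weight always dominates, the global weight ranges 0.05-0.30.
WEIGHT_COMBOS: Dict[str, Tuple[float, float]] = {
    "CB1": (0.95, 0.05),
    "CB2": (0.90, 0.10),
    "CB3": (0.85, 0.15),
    "CB4": (0.80, 0.20),
    "CB5": (0.75, 0.25),
    "CB6": (0.70, 0.30),
}

_BASE_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_CODE[ord(_b)] = _i

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass(frozen=True)
class HybridParams:
    """Parameters of the hybrid distance.

    k            word length in bases (default 6)
    window       window length in bases for the local d² feature (default 100)
    weight_local A, weight on the normalized d² term
    weight_global B, weight on the gred term; A + B must equal 1
    """

    k: int = 6
    window: int = 100
    weight_local: float = 0.9
    weight_global: float = 0.1

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("word length k must be >= 1")
        if self.window < self.k:
            raise ValueError("window must be >= k")
        if not (0.0 <= self.weight_local <= 1.0 and 0.0 <= self.weight_global <= 1.0):
            raise ValueError("weights must lie in [0, 1]")
        if abs(self.weight_local + self.weight_global - 1.0) > 1e-12:
            raise ValueError("weight_local + weight_global must equal 1")

    @classmethod
    def from_combo(cls, name: str, **kwargs) -> "HybridParams":
        """Build params from a named weight combination (CB1..CB6)."""
        try:
            a, b = WEIGHT_COMBOS[name.upper()]
        except KeyError:
            raise ValueError(
                f"unknown weight combination {name!r}; choose from {sorted(WEIGHT_COMBOS)}"
            ) from None
        return cls(weight_local=a, weight_global=b, **kwargs)

    def with_weights(self, weight_local: float, weight_global: float) -> "HybridParams":
        return replace(self, weight_local=weight_local, weight_global=weight_global)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered id list.

    ``kind`` records the scale: raw_d2 (unbounded counts), normalized_d2,
    gred or hybrid (all in [0, 1]). Row/column i corresponds to the i-th
    record of the originating dataset.
    """

    ids: List[str]
    values: np.ndarray
    kind: str = "hybrid"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def validate(self, atol: float = 1e-8) -> None:
        v = self.values
        if not np.allclose(v, v.T, atol=atol):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=atol):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -atol).any():
            raise ValueError("distance matrix has negative entries")
        if self.kind in ("normalized_d2", "gred", "hybrid") and (v > 1 + atol).any():
            raise ValueError(f"{self.kind} matrix has entries above 1")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# word counting


def _word_codes(seq: str, k: int) -> Tuple[np.ndarray, np.ndarray]:
    """Integer codes of every k-word start position, plus a validity mask.

    A word is valid only if all k bases are in {A,C,G,T}; invalid positions
    carry code -1 and must be masked out by the caller.
    """
    arr = _BASE_CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=bool)
    win = sliding_window_view(arr, k)
    valid = (win >= 0).all(axis=1)
    powers = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    codes = win.astype(np.int64) @ powers
    codes[~valid] = -1
    return codes, valid


def count_words(seq: str, k: int) -> Counter:
    """Occurrence counts of every length-k word of ``seq`` over {A,C,G,T}.

    Words containing any other character (N, ambiguity codes, lowercase
    already normalized away upstream) contribute nothing. k longer than the
    sequence yields an empty counter.
    """
    if k < 1:
        raise ValueError("word length k must be >= 1")
    seq = seq.upper()
    _, valid = _word_codes(seq, k)
    return Counter(seq[i : i + k] for i in np.flatnonzero(valid))


def word_freqs(seq: str, k: int) -> Dict[str, float]:
    """Relative frequencies of k-words over the whole sequence.

    Frequencies sum to 1; computed on the entire sequence (the global
    feature), never per window. Raises if the sequence has no valid k-word.
    """
    counts = count_words(seq, k)
    total = sum(counts.values())
    if total == 0:
        raise ValueError(f"sequence has no valid {k}-word")
    return {w: c / total for w, c in counts.items()}


# ---------------------------------------------------------------------------
# local feature: windowed d2


def _window_spans(n_words: int, window: int, k: int) -> Tuple[int, int]:
    """Words per window and number of window start positions.

    ``n_words`` is L - k + 1 for sequence length L. When the sequence is
    shorter than the window the whole sequence is the single window.
    """
    wp = window - k + 1
    if wp >= n_words:
        return n_words, 1
    return wp, n_words - wp + 1


def _integral(m: np.ndarray) -> np.ndarray:
    # int32 is safe: box sums are bounded by len(P) * len(Q) word positions
    out = np.zeros((m.shape[0] + 1, m.shape[1] + 1), dtype=np.int32)
    out[1:, 1:] = m.astype(np.int32).cumsum(axis=0, dtype=np.int32).cumsum(axis=1)
    return out


def _self_window_norms(codes: np.ndarray, valid: np.ndarray, wp: int, span: int) -> np.ndarray:
    """Σ_w c(w)² for every window, via the self-match summed-area table."""
    m = (codes[:, None] == codes[None, :]) & valid[:, None] & valid[None, :]
    ii = _integral(m)
    a = np.arange(span)
    return ii[a + wp, a + wp] - ii[a, a + wp] - ii[a + wp, a] + ii[a, a]


def _min_window_d2(
    cp: np.ndarray,
    vp: np.ndarray,
    cq: np.ndarray,
    vq: np.ndarray,
    window: int,
    k: int,
    pp: Optional[np.ndarray] = None,
    qq: Optional[np.ndarray] = None,
) -> int:
    """Minimum windowed d² between two encoded sequences (exact integers).

    Uses the expansion Σ(c_p − c_q)² = Σc_p² + Σc_q² − 2Σc_p·c_q where each
    term is a rectangular box sum over a word-position match matrix; box
    sums come from summed-area tables, which is bit-identical to recounting
    every window from scratch.  ``pp``/``qq`` allow the per-sequence self
    terms (which do not depend on the partner) to be precomputed once.
    """
    wp, span_p = _window_spans(len(cp), window, k)
    wq, span_q = _window_spans(len(cq), window, k)
    m = (cp[:, None] == cq[None, :]) & vp[:, None] & vq[None, :]
    ii = _integral(m)
    cross = (
        ii[wp : wp + span_p, wq : wq + span_q]
        - ii[0:span_p, wq : wq + span_q]
        - ii[wp : wp + span_p, 0:span_q]
        + ii[0:span_p, 0:span_q]
    )
    if pp is None:
        pp = _self_window_norms(cp, vp, wp, span_p)
    if qq is None:
        qq = _self_window_norms(cq, vq, wq, span_q)
    d2 = pp[:, None] + qq[None, :] - 2 * cross
    return int(d2.min())


def d2_distance(P: ESTRecord, Q: ESTRecord, params: HybridParams = HybridParams()) -> float:
    """Windowed word-count distance between two ESTs.

    The minimum over all pairs of window-length contiguous subsequences
    (stride 1 on both sides) of the summed squared word-count differences.
    Symmetric; 0 whenever the two sequences share an identical window.
    """
    for rec in (P, Q):
        if len(rec.seq) < params.k:
            raise ValueError(
                f"sequence {rec.id!r} is shorter than word length k={params.k}"
            )
    cp, vp = _word_codes(P.seq, params.k)
    cq, vq = _word_codes(Q.seq, params.k)
    return float(_min_window_d2(cp, vp, cq, vq, params.window, params.k))


# ---------------------------------------------------------------------------
# global feature: gred


def gred_distance(P: ESTRecord, Q: ESTRecord, k: int = 6) -> float:
    """Bounded relative-entropy distance between whole-sequence k-mer
    frequency vectors (base-2 Jensen–Shannon divergence).

    0 iff the two frequency vectors are identical; 1 iff their word supports
    are disjoint (completely different ESTs).
    """
    fp = word_freqs(P.seq, k)
    fq = word_freqs(Q.seq, k)
    words = sorted(set(fp) | set(fq))
    p = np.array([fp.get(w, 0.0) for w in words])
    q = np.array([fq.get(w, 0.0) for w in words])
    js = jensenshannon(p, q, base=2) ** 2
    return float(min(max(js, 0.0), 1.0))


def _freq_matrix(ds: ESTDataset, k: int) -> np.ndarray:
    """Dense n × 4^k k-mer frequency matrix for the whole sequences."""
    n_words = 4**k
    freqs = np.zeros((len(ds), n_words), dtype=float)
    for i, rec in enumerate(ds):
        codes, valid = _word_codes(rec.seq, k)
        good = codes[valid]
        if good.size == 0:
            raise ValueError(f"sequence {rec.id!r} has no valid {k}-word")
        np.add.at(freqs[i], good, 1.0)
        freqs[i] /= good.size
    return freqs


def _entropy_rows(f: np.ndarray) -> np.ndarray:
    logs = np.zeros_like(f)
    np.log2(f, out=logs, where=f > 0)
    return -(f * logs).sum(axis=1)


def gred_matrix(ds: ESTDataset, k: int = 6) -> DistanceMatrix:
    """Pairwise gred over a dataset (vectorized mixture-entropy form).

    JS(p, q) = H((p+q)/2) − (H(p) + H(q)) / 2 with base-2 entropies H.
    """
    f = _freq_matrix(ds, k)
    h = _entropy_rows(f)
    n = len(ds)
    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        mix = (f[i][None, :] + f[i + 1 :]) / 2.0
        js = _entropy_rows(mix) - 0.5 * (h[i] + h[i + 1 :])
        out[i, i + 1 :] = js
        out[i + 1 :, i] = js
    np.clip(out, 0.0, 1.0, out=out)
    return DistanceMatrix(ids=ds.ids, values=out, kind="gred")


# ---------------------------------------------------------------------------
# matrix assembly


def d2_matrix(
    ds: ESTDataset, params: HybridParams = HybridParams(), rc: bool = False
) -> DistanceMatrix:
    """Pairwise raw windowed d² over a dataset.

    With ``rc=True`` each pair additionally considers the reverse complement
    of the second sequence and keeps the smaller distance (for unoriented
    EST libraries; off by default — the published formulas compare forward
    strands only).
    """
    n = len(ds)

    def _encode(seq: str):
        codes, valid = _word_codes(seq, params.k)
        wp, span = _window_spans(len(codes), params.window, params.k)
        return codes, valid, _self_window_norms(codes, valid, wp, span)

    enc = []
    enc_rc = []
    for rec in ds:
        if len(rec.seq) < params.k:
            raise ValueError(
                f"sequence {rec.id!r} is shorter than word length k={params.k}"
            )
        enc.append(_encode(rec.seq))
        if rc:
            enc_rc.append(_encode(reverse_complement(rec.seq)))
    out = np.zeros((n, n), dtype=float)
    for i in range(n - 1):
        cp, vp, pp = enc[i]
        for j in range(i + 1, n):
            cq, vq, qq = enc[j]
            d = _min_window_d2(cp, vp, cq, vq, params.window, params.k, pp=pp, qq=qq)
            if rc:
                cr, vr, rr = enc_rc[j]
                d = min(
                    d,
                    _min_window_d2(cp, vp, cr, vr, params.window, params.k, pp=pp, qq=rr),
                )
            out[i, j] = out[j, i] = d
    return DistanceMatrix(ids=ds.ids, values=out, kind="raw_d2")


def minmax_normalize(m: DistanceMatrix) -> DistanceMatrix:
    """Min–max normalization of a raw d² matrix to [0, 1].

    Each off-diagonal entry x maps to (x − d²_min) / (d²_max − d²_min) with
    the extrema taken over all off-diagonal entries; the diagonal stays 0.
    The transformation is linear, so the rank order of distances is
    preserved. If all off-diagonal entries are equal the matrix degenerates
    to all zeros (with a warning).
    """
    v = m.values
    n = m.n
    if n < 2:
        raise ValueError("min-max normalization needs at least 2 sequences")
    off = ~np.eye(n, dtype=bool)
    lo = v[off].min()
    hi = v[off].max()
    out = np.zeros_like(v)
    if hi == lo:
        warnings.warn(
            "all off-diagonal d2 values are equal; normalized matrix is all zeros",
            RuntimeWarning,
            stacklevel=2,
        )
    else:
        out[off] = (v[off] - lo) / (hi - lo)
    return DistanceMatrix(ids=list(m.ids), values=out, kind="normalized_d2")


def combine(nd2: DistanceMatrix, gred: DistanceMatrix, params: HybridParams) -> DistanceMatrix:
    """Weighted hybrid hbd = A · d2'' + B · gred (entrywise).

    Linear in its two inputs at fixed weights, which is what lets parameter
    sweeps re-weight precomputed matrices instead of recomputing them.
    """
    if list(nd2.ids) != list(gred.ids):
        raise ValueError("normalized-d2 and gred matrices cover different ids")
    vals = params.weight_local * nd2.values + params.weight_global * gred.values
    return DistanceMatrix(ids=list(nd2.ids), values=vals, kind="hybrid")


def hybrid_matrix(
    ds: ESTDataset,
    params: HybridParams = HybridParams(),
    rc: bool = False,
    feature: str = "hybrid",
) -> DistanceMatrix:
    """Full hybrid distance matrix for a dataset.

    Steps: (1) local windowed d² for all pairs, (2) global gred for all
    pairs, (3) min–max normalization of the local matrix, (4) weighted
    combination. ``feature='local'`` returns only the normalized d² matrix
    (the windowed-d²-style measure used for comparison harnesses);
    ``feature='global'`` only the gred matrix.
    """
    if len(ds) < 2:
        raise ValueError("need at least 2 sequences")
    if feature not in ("hybrid", "local", "global"):
        raise ValueError("feature must be one of hybrid|local|global")
    if feature == "global":
        return gred_matrix(ds, params.k)
    nd2 = minmax_normalize(d2_matrix(ds, params, rc=rc))
    if feature == "local":
        return nd2
    return combine(nd2, gred_matrix(ds, params.k), params)
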