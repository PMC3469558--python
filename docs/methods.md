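# Methods

## The hybrid distance

`hbdest` scores a pair of ESTs with two complementary statistics and a
convex combination of them.

**Local feature: windowed d².** Both sequences are scanned with every
contiguous window of `window` bases (stride 1; a sequence shorter than the
window is its own single window). For one window pair the distance is
Σ_w (c_p(w) − c_q(w))² over all 4^k words of length `k`; the pair distance
is the minimum over all window pairs. This is the comparison principle of
the established alignment-free EST clustering tools: two ESTs are similar
if they overlap well anywhere. Implementation note: the minimum is computed
exactly, via summed-area tables over the word-position match matrix (the
expansion Σ(c_p−c_q)² = Σc_p² + Σc_q² − 2Σc_p·c_q turns every term into a
rectangular box sum). This is bit-identical to recounting every window —
the test suite asserts exact integer agreement against a naive
all-window-pairs enumeration — at roughly O(|P|·|Q|) per pair instead of
O(|P|·|Q|·W).

Raw d² values are unbounded counts, so the dataset's off-diagonal values
are min–max normalized to [0, 1] before weighting. The diagonal is excluded
from the extrema so that self-distance zeros do not force the minimum;
duplicate ESTs can still legitimately produce d²_min = 0. The degenerate
all-equal case maps to all zeros with a warning.

**Global feature: gred.** A relative-entropy distance between the *whole
sequence* k-mer frequency vectors. The contract: word-frequency based,
symmetric, range [0, 1], 0 for identical frequency vectors, 1 for disjoint
word supports. We implement it as the base-2 Jensen–Shannon divergence,
JS(f^P, f^Q) = H((f^P+f^Q)/2) − (H(f^P)+H(f^Q))/2 — the standard bounded
symmetric divergence satisfying all of these properties without pseudocount
tuning (zero frequencies are handled naturally). The function is a
deliberate strategy point: any other divergence with the same contract can
be swapped in. The matrix path uses the vectorized mixture-entropy form;
the scalar path squares `scipy`'s Jensen–Shannon metric; tests pin the two
against each other and against hand-evaluated values.

**Hybrid.** hbd = A·d²″ + B·gred, A + B = 1, so hbd ∈ [0, 1] with 0 for
identical ESTs. The local weight always dominates (the named grid CB1–CB6
spans B = 0.05…0.30): overlap remains the primary clustering signal, the
global term only adds the sensitivity needed to keep paralogs apart.
Because the combination is linear, parameter sweeps re-weight the two
precomputed matrices instead of recomputing them — exactly, not
approximately.

**Why it works on gene families.** ESTs from different paralogs that share
one exon-length block have d²″ ≈ 0 (some window pair is near-identical) but
a clearly nonzero gred (the rest of their sequences diverged). With B = 0.1
and Eps = 0.1 the hybrid pushes exactly those pairs past the DBSCAN radius,
while same-gene overlapping pairs (d²″ ≈ 0 *and* moderate gred, scaled by
B) stay inside it. Note the hard ceiling: a pair with d²″ = 0 has
hbd = B·gred ≤ B, so the mechanism requires the shared blocks to carry at
least a mismatch or two per window — biologically, paralogous exons are
diverged copies, not perfect duplicates.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `k` | 6 | word length, ≤ 4^k distinct words |
| `window` | 100 bases | local window length; also the minimum overlap that counts as evidence |
| `weight_local` A | 0.9 | weight on normalized d² |
| `weight_global` B | 0.1 | weight on gred |
| `eps` | 0.1 | DBSCAN neighborhood radius in hybrid units (useful range 0.1 ± 0.05) |
| `min_points` | 2 | neighbors (self excluded) required to seed/extend a cluster |
| `min_len` (CLI) | 100 bp | input cleaning: shorter ESTs/mRNAs are dropped |

k = 6 / window = 100 are the standard defaults of the windowed-d² EST
tools; A = 0.9 / B = 0.1 and Eps = 0.1 are the comparative-study settings.
`min_points` = 2 is the weakest density requirement that still
distinguishes clusters from singletons. Word length is shared between the
local and global features by default but independently configurable.

## Clustering procedures

DBSCAN is implemented directly from the two-function formulation (scan +
expand): ESTs are visited in dataset order; an unvisited EST with ≥
`min_points` neighbors within `eps` (neighborhoods exclude the point
itself) opens the next cluster id and the cluster is expanded breadth-first,
merging neighborhoods of core neighbors; unreachable ESTs are labeled −1,
and provisional noise is adopted by a cluster that later reaches it. With
the scan order fixed the procedure is fully deterministic; border points
equidistant to two clusters go to the earlier-created one. The test suite
checks partition identity against a declarative density-reachability
closure and cross-checks core/noise structure against scikit-learn's
DBSCAN (shifting `min_samples` by one because scikit-learn counts the point
itself).

The hierarchical alternative is single linkage on the same matrix with a
flat cut at merge distance ≤ `cut` (default = `eps`), which equals the
connected components of the ≤-cut graph. Single linkage is the natural
match for transitive-overlap EST clustering; size-1 clusters are reported
as −1 to keep the noise convention comparable.

**Jaccard index.** a/(a+b+c) over unordered pairs. A −1 in the *prediction*
is its own singleton (two noise ESTs never co-cluster); a −1 in the *truth*
table is an ordinary label — the convention is intentionally asymmetric and
documented in the tests. All-singletons-on-both-sides (a+b+c = 0) is
defined as 1.

## The synthetic generator

`simulate_family` emulates a curated gene-family EST set: an ancestral
sequence; paralogs derived by independently mutating non-shared regions at
`inter_gene_divergence` (default 0.30) while designated shared blocks
(length ≥ the window, identical offsets across paralogs) mutate at the much
smaller `shared_block_divergence`; ESTs sampled as uniform contiguous
fragments (default 200–800 bp, matching typical single-pass read lengths)
with per-base substitution errors. Defaults keep the shape of real family
datasets (12 genes, ~100 ESTs/gene).

What it does **not** model: indels and chimeric reads (substitution-only
keeps exact-substring/identical-window properties assertable), splicing
isoforms and UTR structure, 3′ sampling bias, repeat content, and quality
values. Passing tests therefore demonstrate the distance measure's
behavior under the shared-block mechanism specifically, not performance on
arbitrary real EST libraries.

Two frozen fixtures (config + seed pinned in `hbdest.synthetic`) back the
end-to-end tests, scaled to desk size:

- `fixture_easy` — 5 genes × 24 ESTs (120 ESTs, 300–800 bp), no shared
  blocks, divergence 0.35: genes are well separated and the default
  pipeline must recover the truth partition exactly (Jaccard 1.0), DBSCAN
  and single linkage agreeing.
- `fixture_family` — 6 genes × 25 ESTs (150 ESTs, 250–700 bp), two shared
  130 bp blocks at 2 % per-copy divergence: the local-only configuration
  merges five genes into one cluster (Jaccard 1800/8050 ≈ 0.224) while the
  hybrid at defaults recovers the truth exactly. Both values were measured
  once at fixture-freeze time, verified against the brute-force oracles,
  and pinned.

The freeze-time calibration of `shared_block_divergence` deserves a note:
at ≲ 1 % pairwise divergence the shared blocks contain perfectly identical
windows, d²″ hits 0 for cross-gene pairs and *no* [0,1]-bounded global term
weighted at B = 0.1 can lift them past Eps = 0.1 (the ceiling above) — the
hybrid then fails exactly as the local measure does. At ≳ 6 % every window
pair carries several mismatches and even the local measure separates the
genes. The fixture sits in the regime between, which is where the
gene-family problem actually lives.

## Numerical choices and degenerate inputs

- d² is integer arithmetic throughout (int32 summed-area tables; box sums
  are bounded by |P|·|Q|); oracle agreement is exact equality, not
  approximate.
- Words containing non-ACGT characters are excluded from counts and
  frequencies (no pseudocounts invented for ambiguity codes); a sequence
  with no valid k-word is an error for the global feature.
- Window stride is 1 on both sequences — the exhaustive minimum. A
  coarser stride would be faster and is deliberately not offered, since it
  changes the measure.
- Forward strand only by default; `rc=True` (CLI `--rc`) takes the minimum
  over the partner's two orientations for unoriented libraries.
- Matrix TSV round-trips at 10 significant digits (read∘write ≈ id within
  1e-6); outputs are written atomically (temp file + rename).
- gred values are clipped to [0, 1] against ~1e-16 float residue from the
  entropy computation.

## Problem sizes and runtime

All shipped computations are sized for a single CPU: the fixtures are
120/150 ESTs (≈ 7 000–11 000 pairs, under a minute each for the full
matrix), the oracle comparisons use 200 random sequence pairs (d²), 500
pairs (gred), and 100+ random matrices with n ≤ 30 (DBSCAN). The pairwise
d² matrix is the dominant cost and scales as O(n²·L²); datasets in the
thousands of ESTs are feasible but take correspondingly longer.

## Known limitations

- The global divergence is one defensible realization of its contract;
  other bounded word-frequency divergences could rank borderline pairs
  differently.
- The B ≤ 0.3 weight regime presumes the local feature remains the primary
  signal; datasets whose confusion is *not* block-structured (e.g. global
  compositional convergence) are out of scope.
- DBSCAN border-point assignment is scan-order dependent (first cluster
  wins); partitions restricted to core points are order-invariant, which is
  what the tests guarantee.
- No indel model in the simulator means measured robustness to real
  sequencing indels is unknown.
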