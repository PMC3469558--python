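"""Synthetic gene-family EST datasets with ground truth.

The clustering problem this package targets is hard precisely when several
paralogous genes of one family share exon-length blocks of near-identical
sequence while the rest of their bodies have diverged: a purely local,
window-based distance then co-clusters ESTs from different genes.  The
simulator reproduces that structure directly:

1. draw a random ancestral gene sequence;
2. derive each paralog by copying designated shared blocks with a small
   per-base substitution rate and mutating the remainder independently at a
   much larger rate;
3. sample each EST as a contiguous fragment of its source gene (uniform
   start, uniform length in a 200–800 bp style range);
4. apply per-base sequencing substitution errors.

Substitution-only (no indels), so exact-substring and identical-window
properties remain assertable.  Truth label = source gene.  Everything is
reproducible from the config seed.

Defaults mirror the shape of real curated gene-family EST sets: about a
dozen genes per family, on the order of a hundred ESTs per gene, fragment
lengths 200–800 bases.  The two frozen fixtures used in tests are
scaled-down instances of the same generator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Dict, List, Tuple, Union

import numpy as np

from .io import ESTDataset, ESTRecord

__all__ = [
    "SyntheticFamilyConfig",
    "simulate_family",
    "fixture_easy",
    "fixture_family",
    "EASY_CONFIG",
    "FAMILY_CONFIG",
]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SyntheticFamilyConfig:
    """Parameters of the gene-family EST simulator.

    n_genes                paralogous genes in the family
    gene_len               gene body length in bases
    n_exons                shared exon-like blocks copied across paralogs
    shared_block_len       length of each shared block (>= 100 so a whole
                           comparison window fits inside it)
    inter_gene_divergence  per-base substitution probability applied
                           independently per paralog outside shared blocks
    shared_block_divergence  per-base substitution probability inside shared
                           blocks (small; pairwise divergence is about twice
                           this rate)
    ests_per_gene          EST count per gene, fixed int or (lo, hi) range
    est_len_range          EST fragment length bounds in bases, inclusive
    error_rate             per-base sequencing substitution error on ESTs
    seed                   RNG seed; the whole dataset is a pure function
                           of the config
    """

    n_genes: int = 12
    gene_len: int = 3000
    n_exons: int = 2
    shared_block_len: int = 120
    inter_gene_divergence: float = 0.30
    shared_block_divergence: float = 0.01
    ests_per_gene: Union[int, Tuple[int, int]] = 100
    est_len_range: Tuple[int, int] = (200, 800)
    error_rate: float = 0.002
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 2:
            raise ValueError("need at least 2 genes")
        lo, hi = self.est_len_range
        if not (100 <= lo <= hi <= self.gene_len):
            raise ValueError("est_len_range must satisfy 100 <= lo <= hi <= gene_len")
        for name in ("inter_gene_divergence", "shared_block_divergence", "error_rate"):
            p = getattr(self, name)
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"{name} must be a probability")
        if self.n_exons > 0 and self.shared_block_len < 1:
            raise ValueError("shared_block_len must be positive when n_exons > 0")
        if self.n_exons * self.shared_block_len > self.gene_len:
            raise ValueError("shared blocks exceed the gene length")

    @classmethod
    def from_json(cls, path) -> "SyntheticFamilyConfig":
        with open(path) as fh:
            data = json.load(fh)
        if "est_len_range" in data:
            data["est_len_range"] = tuple(data["est_len_range"])
        if isinstance(data.get("ests_per_gene"), list):
            data["ests_per_gene"] = tuple(data["ests_per_gene"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def _block_starts(cfg: SyntheticFamilyConfig) -> List[int]:
    """Evenly spaced non-overlapping shared-block offsets (identical across
    paralogs)."""
    if cfg.n_exons == 0:
        return []
    gap_total = cfg.gene_len - cfg.n_exons * cfg.shared_block_len
    gap = gap_total // (cfg.n_exons + 1)
    starts = [gap + i * (cfg.shared_block_len + gap) for i in range(cfg.n_exons)]
    if starts[-1] + cfg.shared_block_len > cfg.gene_len:
        raise ValueError("shared blocks exceed the gene length")
    return starts


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base with probability ``rate`` (always to a different
    base)."""
    out = arr.copy()
    if rate <= 0 or out.size == 0:
        return out
    hit = np.flatnonzero(rng.random(out.size) < rate)
    if hit.size:
        out[hit] = (out[hit] + rng.integers(1, 4, size=hit.size)) % 4
    return out


def _decode(arr: np.ndarray) -> str:
    return _BASES[arr].tobytes().decode("ascii")


def simulate_family(cfg: SyntheticFamilyConfig) -> Tuple[ESTDataset, Dict[str, str]]:
    """Generate one gene-family EST dataset plus its truth label table.

    Returns the dataset (records grouped by gene, generation order) and a
    mapping id -> gene label ("gene01", ...). Also attaches the paralog
    sequences on the returned dataset as ``ds.gene_seqs`` for inspection.
    """
    rng = np.random.default_rng(cfg.seed)
    ancestor = rng.integers(0, 4, size=cfg.gene_len, dtype=np.int8)
    starts = _block_starts(cfg)
    in_block = np.zeros(cfg.gene_len, dtype=bool)
    for s in starts:
        in_block[s : s + cfg.shared_block_len] = True

    genes: List[np.ndarray] = []
    for _ in range(cfg.n_genes):
        g = ancestor.copy()
        g[~in_block] = _mutate(ancestor[~in_block], cfg.inter_gene_divergence, rng)
        g[in_block] = _mutate(ancestor[in_block], cfg.shared_block_divergence, rng)
        genes.append(g)

    lo, hi = cfg.est_len_range
    records: List[ESTRecord] = []
    truth: Dict[str, str] = {}
    for gi, gene in enumerate(genes, 1):
        label = f"gene{gi:02d}"
        if isinstance(cfg.ests_per_gene, int):
            count = cfg.ests_per_gene
        else:
            count = int(rng.integers(cfg.ests_per_gene[0], cfg.ests_per_gene[1] + 1))
        for ei in range(1, count + 1):
            length = int(rng.integers(lo, hi + 1))
            start = int(rng.integers(0, cfg.gene_len - length + 1))
            frag = _mutate(gene[start : start + length], cfg.error_rate, rng)
            rid = f"{label}_est{ei:03d}"
            records.append(ESTRecord(id=rid, seq=_decode(frag)))
            truth[rid] = label

    ds = ESTDataset(records)
    ds.gene_seqs = {f"gene{gi:02d}": _decode(g) for gi, g in enumerate(genes, 1)}
    return ds, truth


# ---------------------------------------------------------------------------
# frozen fixtures
#
# Both configs were fixed once (seed included) after verifying their
# documented contracts: EASY_CONFIG yields well-separated genes that the
# default hybrid pipeline recovers exactly; FAMILY_CONFIG yields paralogs
# sharing near-identical >=100 bp blocks, so a local-only distance
# co-clusters ESTs across genes while the hybrid separates them better.

EASY_CONFIG = SyntheticFamilyConfig(
    n_genes=5,
    gene_len=1000,
    n_exons=0,
    shared_block_len=0,
    inter_gene_divergence=0.35,
    shared_block_divergence=0.0,
    ests_per_gene=24,
    est_len_range=(300, 800),
    error_rate=0.002,
    seed=20120817,
)

FAMILY_CONFIG = SyntheticFamilyConfig(
    n_genes=6,
    gene_len=1500,
    n_exons=2,
    shared_block_len=130,
    inter_gene_divergence=0.30,
    shared_block_divergence=0.02,
    ests_per_gene=25,
    est_len_range=(250, 700),
    error_rate=0.002,
    seed=1,
)


def fixture_easy() -> Tuple[ESTDataset, Dict[str, str]]:
    """Frozen well-separated family: no shared blocks, deep inter-gene
    divergence; the default pipeline recovers the truth partition."""
    return simulate_family(EASY_CONFIG)


def fixture_family() -> Tuple[ESTDataset, Dict[str, str]]:
    """Frozen hard family: paralogs share two near-identical 130 bp blocks,
    so a window-only comparison sees cross-gene distances near 0."""
    return simulate_family(FAMILY_CONFIG)
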