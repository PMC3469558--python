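"""Reading and writing of the formats the pipeline touches.

Three carriers: multi-FASTA nucleotide sequences (:class:`ESTDataset`),
two-column TSV label tables mapping sequence id to gene/cluster label, and
square TSV distance matrices with an id header row and id-leading rows.

Record order is load-bearing throughout the package: row/column ``i`` of a
distance matrix always refers to record ``i`` of the dataset it was computed
from, and the clustering scan order is the dataset order.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping

import numpy as np
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "ESTRecord",
    "ESTDataset",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "read_matrix",
    "write_matrix",
]


@dataclass(frozen=True)
class ESTRecord:
    """A single EST/mRNA sequence: unique ``id`` plus uppercase DNA ``seq``.

    Characters outside {A,C,G,T} (IUPAC ambiguity codes, N) are retained in
    the sequence but any k-word containing them is excluded from counting by
    the distance layer.
    """

    id: str
    seq: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ESTRecord id must be non-empty")
        if len(self.seq) < 1:
            raise ValueError(f"ESTRecord {self.id!r} has an empty sequence")

    def __len__(self) -> int:
        return len(self.seq)


class ESTDataset:
    """Ordered collection of :class:`ESTRecord` with unique ids.

    The record order defines the row order of every distance matrix computed
    from the dataset and the scan order of the clustering procedures.
    """

    def __init__(self, records: Iterable[ESTRecord]):
        self.records: List[ESTRecord] = list(records)
        seen: Dict[str, int] = {}
        for i, rec in enumerate(self.records):
            if rec.id in seen:
                raise ValueError(f"duplicate sequence id {rec.id!r}")
            seen[rec.id] = i
        self._index = seen

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> List[str]:
        return [r.id for r in self.records]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[ESTRecord]:
        return iter(self.records)

    def __getitem__(self, key) -> ESTRecord:
        if isinstance(key, str):
            return self.records[self._index[key]]
        return self.records[key]

    def __contains__(self, rid: str) -> bool:
        return rid in self._index

    def __eq__(self, other) -> bool:
        if not isinstance(other, ESTDataset):
            return NotImplemented
        return self.records == other.records

    def __repr__(self) -> str:
        return f"ESTDataset(n={self.n})"


def read_fasta(path, min_len: int = 0) -> ESTDataset:
    """Read a multi-FASTA file into an :class:`ESTDataset`.

    Sequences are uppercased; records shorter than ``min_len`` are dropped
    (the field's cleaning rule removes ESTs/mRNAs under 100 bp before
    clustering — the command line applies that default, the library does
    not). The number of dropped records is logged.
    """
    records: List[ESTRecord] = []
    dropped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.strip():
                if not line.startswith(">"):
                    raise ValueError(
                        f"malformed FASTA in {path}: sequence data before "
                        f"first header at line {lineno}"
                    )
                break
    try:
        parsed = list(SeqIO.parse(str(path), "fasta"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    for rec in parsed:
        seq = str(rec.seq).upper()
        if len(seq) < min_len:
            dropped += 1
            continue
        records.append(ESTRecord(id=rec.id, seq=seq))
    if dropped:
        logger.info("read_fasta: dropped %d record(s) shorter than %d bp", dropped, min_len)
    return ESTDataset(records)


def write_fasta(ds: ESTDataset, path, width: int = 70) -> None:
    """Write a dataset as multi-FASTA with fixed line wrapping (atomic)."""
    lines: List[str] = []
    for rec in ds:
        lines.append(f">{rec.id}")
        for i in range(0, len(rec.seq), width):
            lines.append(rec.seq[i : i + width])
    _atomic_write(path, "\n".join(lines) + "\n")


def read_labels(path) -> Dict[str, str]:
    """Read a two-column TSV (id, label) into a dict; header row optional.

    A header is recognised as a first row whose columns are literally
    ``id`` and ``label`` (case-insensitive). Duplicate ids with conflicting
    labels are an error; an empty file is an error.
    """
    table: Dict[str, str] = {}
    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"empty label table: {path}")
    start = 0
    first = [c.strip() for c in rows[0].split("\t")]
    if len(first) >= 2 and first[0].lower() == "id" and first[1].lower() == "label":
        start = 1
    for lineno, row in enumerate(rows[start:], start + 1):
        cols = [c.strip() for c in row.split("\t")]
        if len(cols) < 2:
            raise ValueError(f"{path}: line {lineno}: expected two tab-separated columns")
        rid, label = cols[0], cols[1]
        if rid in table and table[rid] != label:
            raise ValueError(
                f"{path}: conflicting labels for id {rid!r}: {table[rid]!r} vs {label!r}"
            )
        table[rid] = label
    if not table:
        raise ValueError(f"empty label table: {path}")
    return table


def write_labels(labels: Mapping[str, object], path) -> None:
    """Write an id → label mapping as two-column TSV with a header (atomic)."""
    lines = ["id\tlabel"] + [f"{rid}\t{lab}" for rid, lab in labels.items()]
    _atomic_write(path, "\n".join(lines) + "\n")


def write_matrix(m, path) -> None:
    """Write a square distance matrix as TSV (atomic).

    First row: tab-joined ids. Each following row: id then the n values at
    10 significant digits, so that ``read_matrix(write_matrix(m))``
    reproduces the matrix well within 1e-6 per entry.
    """
    ids = list(m.ids)
    vals = np.asarray(m.values, dtype=float)
    lines = ["\t".join(ids)]
    for rid, row in zip(ids, vals):
        lines.append(rid + "\t" + "\t".join(f"{v:.10g}" for v in row))
    _atomic_write(path, "\n".join(lines) + "\n")


def read_matrix(path, kind: str = "hybrid"):
    """Read a square TSV distance matrix written by :func:`write_matrix`."""
    from .distance import DistanceMatrix  # local import to avoid a cycle

    with open(path) as fh:
        rows = [line.rstrip("\n") for line in fh if line.strip()]
    if not rows:
        raise ValueError(f"empty matrix file: {path}")
    ids = rows[0].split("\t")
    n = len(ids)
    if len(rows) - 1 != n:
        raise ValueError(f"{path}: header lists {n} ids but file has {len(rows) - 1} rows")
    values = np.zeros((n, n), dtype=float)
    for i, row in enumerate(rows[1:]):
        cols = row.split("\t")
        if cols[0] != ids[i]:
            raise ValueError(f"{path}: row {i + 1} id {cols[0]!r} does not match header {ids[i]!r}")
        if len(cols) - 1 != n:
            raise ValueError(f"{path}: row {i + 1} has {len(cols) - 1} values, expected {n}")
        values[i] = [float(c) for c in cols[1:]]
    return DistanceMatrix(ids=ids, values=values, kind=kind)


def _atomic_write(path, text: str) -> None:
    path = str(path)
    d = os.path.dirname(path) or "."
    fd, tmp = tempfile.mkstemp(dir=d, prefix=".tmp-", text=True)
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise
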