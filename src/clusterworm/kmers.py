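"""K-mer counting: decompose reads into unique k-mers with abundances.

This is the pipeline's first map/collate/reduce cycle: the map emits one
pair per valid k-length window of each read (key = k-mer, empty value),
collate groups occurrences by k-mer, and the reduce counts them, dropping
k-mers below the abundance floor.  The result is the node set V of the
de Bruijn graph with abundances C.

Two strand modes are supported.  ``strand_specific`` (the default) counts
k-mers exactly as read; ``double_stranded`` folds every k-mer onto its
canonical form (the lexicographic minimum of the k-mer and its reverse
complement), as appropriate for libraries that do not preserve transcript
orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .engine import Engine
from .errors import DataError
from .seqio import Read

logger = logging.getLogger(__name__)

__all__ = [
    "KmerTable",
    "valid_kmers",
    "canonical",
    "reverse_complement",
    "count_kmers",
]

STRAND_SPECIFIC = "strand_specific"
DOUBLE_STRANDED = "double_stranded"

_COMP = str.maketrans("ACGT", "TGCA")
_ACGT = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def canonical(kmer: str) -> str:
    """Lexicographic minimum of a k-mer and its reverse complement."""
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def valid_kmers(read: Read | str, k: int) -> list[tuple[int, str]]:
    """All (start, k-mer) windows of the read over pure ACGT, left to
    right; windows touching an N (or any non-ACGT base) are skipped."""
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    seq = read.sequence if isinstance(read, Read) else read
    n = len(seq)
    out: list[tuple[int, str]] = []
    if n < k:
        return out
    # rightmost invalid base at/before each position gates the window
    last_bad = -1
    for i, base in enumerate(seq):
        if base not in _ACGT:
            last_bad = i
        start = i - k + 1
        if start >= 0 and last_bad < start:
            out.append((start, seq[start:i + 1]))
    return out


@dataclass
class KmerTable:
    """Unique k-mers with abundances (graph nodes V, abundances C)."""

    entries: dict[str, int]
    k: int
    mode: str = STRAND_SPECIFIC

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, kmer: str) -> bool:
        return kmer in self.entries

    def to_tsv(self, path: str | Path) -> None:
        """Dump as ``kmer<TAB>count`` sorted by k-mer, with a header line
        recording k and mode so stage-wise runs can validate consistency."""
        with open(path, "wt") as fh:
            fh.write(f"#k={self.k}\tmode={self.mode}\n")
            for kmer in sorted(self.entries):
                fh.write(f"{kmer}\t{self.entries[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "KmerTable":
        entries: dict[str, int] = {}
        k = None
        mode = STRAND_SPECIFIC
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.partition("=")
                        if key == "k":
                            k = int(val)
                        elif key == "mode":
                            mode = val
                    continue
                try:
                    kmer, count = line.split("\t")
                    entries[kmer] = int(count)
                except ValueError as exc:
                    raise DataError(
                        f"{path}: line {lineno}: bad k-mer table row") from exc
        if k is None:
            if not entries:
                raise DataError(f"{path}: empty k-mer table with no header")
            k = len(next(iter(entries)))
        return cls(entries=entries, k=k, mode=mode)


def count_kmers(
    reads: Iterable[Read],
    k: int,
    mode: str = STRAND_SPECIFIC,
    min_kmer_cov: int = 1,
    engine: Engine | None = None,
) -> KmerTable:
    """Count every k-mer occurrence across the reads in one
    map → collate → reduce cycle.

    Abundance = number of occurrences (after canonicalisation in
    double-stranded mode); entries below ``min_kmer_cov`` are dropped.  The
    result is independent of read order, worker count and pagesize.
    """
    if mode not in (STRAND_SPECIFIC, DOUBLE_STRANDED):
        raise ValueError(f"unknown strand mode: {mode!r}")
    own = engine is None
    eng = engine or Engine()
    skipped = 0

    ds = mode == DOUBLE_STRANDED

    def emit_kmers(read: Read):
        wins = valid_kmers(read, k)
        if not wins and len(read.sequence) < k:
            nonlocal skipped
            skipped += 1
        if ds:
            return [(canonical(km).encode(), b"") for _, km in wins]
        return [(km.encode(), b"") for _, km in wins]

    def count(key: bytes, values: list[bytes]):
        if len(values) >= min_kmer_cov:
            return [(key, str(len(values)).encode())]
        return []

    try:
        kv = eng.map(reads, emit_kmers)
        counted = eng.reduce(eng.collate(kv), count)
        entries = {k_.decode(): int(v) for k_, v in counted.iter_pairs()}
        counted.close()
    finally:
        if own:
            eng.close()
    if skipped:
        logger.info("skipped %d reads shorter than k=%d", skipped, k)
    logger.info("counted %d unique k-mers (k=%d, %s, min_cov=%d)",
                len(entries), k, mode, min_kmer_cov)
    return KmerTable(entries=entries, k=k, mode=mode)
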