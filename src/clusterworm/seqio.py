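"""Sequence I/O: FASTA/FASTQ reading (plain or gzip), read-file sharding,
and contig FASTA output.

Reads are normalised on ingest: uppercased, RNA ``U`` mapped to ``T``, and
any character outside ``ACGTN`` rejected.  FASTQ qualities are parsed and
discarded — the assembler works from base calls only.  Paired-end files are
consumed as a flat read stream; both mates contribute k-mers independently.
"""

from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Iterator

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import DataError

logger = logging.getLogger(__name__)

__all__ = ["Read", "read_sequences", "split_reads", "write_contigs_fasta"]

_VALID = frozenset("ACGTN")
_NORM = str.maketrans("acgtun", "ACGTTN")


@dataclass(frozen=True, order=True)
class Read:
    """A sequencing read: identifier and normalised base string over ACGTN."""

    id: str
    sequence: str


def _open_text(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _detect_format(fh: IO[str], path: Path) -> str | None:
    first = fh.read(1)
    fh.seek(0)
    if first == "":
        return None
    if first == ">":
        return "fasta"
    if first == "@":
        return "fastq"
    raise DataError(
        f"{path}: line 1: cannot detect format "
        f"(expected '>' for FASTA or '@' for FASTQ, saw {first!r})")


def _normalise(seq: str, rec_id: str, path: Path, line: int) -> str:
    s = seq.translate(_NORM).upper().replace("U", "T")
    if not s:
        raise DataError(f"{path}: line {line}: record {rec_id!r} has an empty sequence")
    bad = set(s) - _VALID
    if bad:
        raise DataError(
            f"{path}: line {line}: record {rec_id!r} contains invalid "
            f"characters {sorted(bad)} (only ACGTN/U allowed)")
    return s


def _iter_records(path: str | Path) -> Iterator[tuple[str, str, str, str | None]]:
    """Yield (fmt, title, raw_sequence, quality-or-None) preserving enough
    of each record to re-emit it verbatim when sharding."""
    path = Path(path)
    if not path.exists():
        raise DataError(f"input file not found: {path}")
    with _open_text(path) as fh:
        fmt = _detect_format(fh, path)
        if fmt is None:
            logger.warning("empty input file: %s", path)
            return
        if fmt == "fasta":
            try:
                for title, seq in SimpleFastaParser(fh):
                    yield fmt, title, seq, None
            except ValueError as exc:
                raise DataError(f"{path}: malformed FASTA record: {exc}") from exc
        else:
            idx = 0
            try:
                for title, seq, qual in FastqGeneralIterator(fh):
                    yield fmt, title, seq, qual
                    idx += 1
            except ValueError as exc:
                raise DataError(
                    f"{path}: line {4 * idx + 1}: malformed FASTQ record: {exc}"
                ) from exc


def read_sequences(path: str | Path) -> Iterator[Read]:
    """Stream reads from a FASTA/FASTQ file (gzip transparent, format
    auto-detected from the first character), normalised to ACGTN.

    Malformed records are fatal with the file position reported; an empty
    file yields an empty stream with a warning.
    """
    path = Path(path)
    line = 1
    for fmt, title, seq, qual in _iter_records(path):
        rec_id = title.split()[0] if title.split() else title
        yield Read(rec_id, _normalise(seq, rec_id, path, line))
        line += 4 if fmt == "fastq" else 2


def split_reads(path: str | Path, n_shards: int, out_dir: str | Path) -> list[Path]:
    """Split a read file into ``n_shards`` files of the same dialect,
    assigning records round-robin by index, so shard sizes differ by at
    most one read and record boundaries are never split."""
    if n_shards < 1:
        raise ValueError(f"n_shards must be >= 1, got {n_shards}")
    path = Path(path)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    gz = path.suffix == ".gz"
    stem = path.name[:-3] if gz else path.name
    base, dot, ext = stem.rpartition(".")
    if not dot:
        base, ext = stem, "fa"
    suffix = f".{ext}" + (".gz" if gz else "")

    paths = [out_dir / f"{base}.shard{i:03d}{suffix}" for i in range(n_shards)]
    handles = [
        gzip.open(p, "wt") if gz else open(p, "wt")  # noqa: SIM115 - closed below
        for p in paths
    ]
    try:
        for idx, (fmt, title, seq, qual) in enumerate(_iter_records(path)):
            fh = handles[idx % n_shards]
            if fmt == "fasta":
                fh.write(f">{title}\n{seq}\n")
            else:
                fh.write(f"@{title}\n{seq}\n+\n{qual}\n")
    finally:
        for fh in handles:
            fh.close()
    return paths


def write_contigs_fasta(contigs: Iterable, path: str | Path) -> None:
    """Write contigs as 60-column-wrapped FASTA.

    Header per record: ``cluster<Z>_contig<i> len=<L> cov=<mean k-mer
    abundance, 2 decimals>`` where ``i`` counts contigs within the cluster
    in assembly order.
    """
    path = Path(path)
    index: dict[int, int] = {}
    try:
        with open(path, "wt") as fh:
            for contig in contigs:
                i = index.get(contig.zone, 0)
                index[contig.zone] = i + 1
                cov = sum(contig.coverage) / len(contig.coverage)
                fh.write(
                    f">cluster{contig.zone}_contig{i} "
                    f"len={len(contig.sequence)} cov={cov:.2f}\n")
                for off in range(0, len(contig.sequence), 60):
                    fh.write(contig.sequence[off:off + 60] + "\n")
    except OSError as exc:
        raise DataError(f"cannot write contig FASTA to {path}: {exc}") from exc
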