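"""Synthetic transcripts and reads with controlled structure.

The generator stands in for an RNA-Seq experiment at desk scale: a set of
random transcript sequences, and reads sampled from them either at uniform
random start positions to a target mean coverage, or in an exhaustive
"tiling" mode where every start position is emitted a fixed number of
times.  Tiling with zero errors makes perfect transcript recovery a
deterministic requirement rather than a statistical one, which is how the
end-to-end tests are phrased.  Substitution errors are applied i.i.d. per
base (no indels) — enough to exercise the low-abundance error branches
that the abundance floor and edge filter must remove.

All randomness flows through :class:`random.Random` seeded with a caller
integer (the Mersenne Twister integer protocol, reproducible across
platforms and Python versions).
"""

from __future__ import annotations

import logging
import math
import random
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .seqio import Read

logger = logging.getLogger(__name__)

__all__ = [
    "SyntheticSet",
    "generate_transcripts",
    "simulate_reads",
    "tile_reads",
    "write_transcripts_fasta",
    "write_reads_fastq",
]

_BASES = "ACGT"
_OTHER = {b: _BASES.replace(b, "") for b in _BASES}


@dataclass
class SyntheticSet:
    """A reproducible bundle of transcripts, reads, and the parameters
    that produced them."""

    transcripts: list[str]
    reads: list[Read]
    params: dict


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(len(seq) - k + 1)}


def generate_transcripts(
    n: int,
    length: int,
    k: int = 25,
    disjoint_spectra: bool = True,
    seed: int = 0,
    max_tries: int = 200,
) -> list[str]:
    """Random ACGT transcripts; with ``disjoint_spectra`` each transcript
    is regenerated until it repeats no internal k-mer and shares no k-mer
    with any earlier transcript.

    Infeasible parameter combinations (expected k-mer collision load too
    high for rejection sampling to terminate promptly) are fatal with
    guidance.
    """
    if length < k:
        raise ValueError(f"transcript length {length} must be >= k={k}")
    total_kmers = n * (length - k + 1)
    if disjoint_spectra and total_kmers ** 2 / 4 ** k > 0.5:
        raise ValueError(
            f"disjoint k-mer spectra are infeasible for n={n}, length={length}, "
            f"k={k}: expected collision load {(total_kmers ** 2 / 4 ** k):.2f} "
            "is too high — raise k or lower n/length")
    rng = random.Random(seed)
    transcripts: list[str] = []
    seen: set[str] = set()
    for idx in range(n):
        for attempt in range(max_tries):
            seq = "".join(rng.choice(_BASES) for _ in range(length))
            if not disjoint_spectra:
                break
            kms = _kmer_set(seq, k)
            if len(kms) == length - k + 1 and not (kms & seen):
                seen |= kms
                break
        else:
            raise ValueError(
                f"could not generate transcript {idx} with a disjoint k-mer "
                f"spectrum in {max_tries} tries; parameters too dense")
        transcripts.append(seq)
    return transcripts


def _mutate(seq: str, error_rate: float, rng: random.Random) -> str:
    if error_rate <= 0:
        return seq
    chars = list(seq)
    for i, b in enumerate(chars):
        if rng.random() < error_rate:
            chars[i] = rng.choice(_OTHER[b])
    return "".join(chars)


def simulate_reads(
    transcripts: Sequence[str],
    read_length: int = 100,
    coverage: float = 30.0,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Read]:
    """Sample reads at uniform random start positions until each
    transcript reaches the target mean coverage, applying substitution
    errors i.i.d. at ``error_rate``."""
    if any(read_length > len(t) for t in transcripts):
        raise ValueError("read_length exceeds the shortest transcript")
    rng = random.Random(seed)
    reads: list[Read] = []
    for ti, t in enumerate(transcripts):
        n_reads = math.ceil(coverage * len(t) / read_length)
        for ri in range(n_reads):
            start = rng.randrange(len(t) - read_length + 1)
            seq = _mutate(t[start:start + read_length], error_rate, rng)
            reads.append(Read(f"t{ti}_r{ri}_p{start}", seq))
    return reads


def tile_reads(
    transcripts: Sequence[str],
    read_length: int = 100,
    copies: int = 1,
    error_rate: float = 0.0,
    seed: int = 0,
) -> list[Read]:
    """Exhaustive tiling: every start position of every transcript emitted
    ``copies`` times, in deterministic order.

    With ``error_rate=0`` the read set's k-mer spectrum (k ≤ read length)
    equals the transcripts' exactly, so the pipeline must recover every
    transcript perfectly; with errors the tiling still guarantees deep,
    position-uniform interior coverage.
    """
    if any(read_length > len(t) for t in transcripts):
        raise ValueError("read_length exceeds the shortest transcript")
    rng = random.Random(seed)
    reads: list[Read] = []
    for ti, t in enumerate(transcripts):
        for start in range(len(t) - read_length + 1):
            for c in range(copies):
                seq = _mutate(t[start:start + read_length], error_rate, rng)
                reads.append(Read(f"t{ti}_p{start}_c{c}", seq))
    return reads


def write_transcripts_fasta(transcripts: Iterable[str], path: str | Path) -> None:
    with open(path, "wt") as fh:
        for i, t in enumerate(transcripts):
            fh.write(f">transcript{i}\n{t}\n")


def write_reads_fastq(reads: Iterable[Read], path: str | Path) -> None:
    """FASTQ with uniform dummy qualities ('I')."""
    with open(path, "wt") as fh:
        for r in reads:
            fh.write(f"@{r.id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
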