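"""De Bruijn graph edge extraction and abundance-based edge filtering.

Edges are *read-supported*: an edge (a → b) exists only where the k-mers at
adjacent read positions i and i+1 are both valid and both survive in the
k-mer table; its abundance CE counts those adjacent co-occurrences across
all reads.  No trial extensions are made — the graph contains exactly the
overlaps the reads witnessed.

The filter keeps, for every node, only its strongest candidates: an edge
survives when its CE is maximal among the source's outgoing (3′) edges AND
maximal among the target's incoming (5′) edges (ties at the maximum are all
retained).  This prunes low-abundance branches — typically sequencing-error
spurs — before clustering, which keeps the subsequent connected components
compact and comparable in size.  An OR variant (maximal at either endpoint)
is available for comparison; AND splits more aggressively and is the
default.  Note the AND rule can delete a node's only out-edge when that
edge is non-maximal at its target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .engine import Engine
from .errors import DataError
from .kmers import DOUBLE_STRANDED, KmerTable, canonical, valid_kmers
from .seqio import Read

logger = logging.getLogger(__name__)

__all__ = ["Edge", "EdgeTable", "extract_edges", "filter_edges"]

FILTER_AND = "and"
FILTER_OR = "or"


@dataclass(frozen=True)
class Edge:
    """Directed k−1-overlap edge between k-mer nodes with abundance CE.

    In double-stranded mode the endpoints are canonical forms and
    ``orientations`` records which strand combinations ('F'orward /
    'R'everse per endpoint) were observed; the suffix/prefix overlap then
    holds in the observed read orientation rather than between the
    canonical strings themselves.
    """

    source: str
    target: str
    ce: int
    orientations: frozenset = frozenset()


@dataclass
class EdgeTable:
    """Edge set keyed by (source, target)."""

    edges: dict[tuple[str, str], Edge]
    k: int

    def __len__(self) -> int:
        return len(self.edges)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        return pair in self.edges

    def ce(self, source: str, target: str) -> int:
        return self.edges[(source, target)].ce

    def to_tsv(self, path: str | Path) -> None:
        """Dump as ``source<TAB>target<TAB>CE`` sorted by pair."""
        with open(path, "wt") as fh:
            fh.write(f"#k={self.k}\n")
            for (s, t) in sorted(self.edges):
                fh.write(f"{s}\t{t}\t{self.edges[(s, t)].ce}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "EdgeTable":
        edges: dict[tuple[str, str], Edge] = {}
        k = None
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
                    continue
                try:
                    s, t, ce = line.split("\t")
                    edges[(s, t)] = Edge(s, t, int(ce))
                except ValueError as exc:
                    raise DataError(
                        f"{path}: line {lineno}: bad edge table row") from exc
        if k is None:
            if not edges:
                raise DataError(f"{path}: empty edge table with no header")
            k = len(next(iter(edges))[0])
        return cls(edges=edges, k=k)


def extract_edges(
    reads: Iterable[Read],
    k: int,
    kmer_table: KmerTable,
    mode: str | None = None,
    engine: Engine | None = None,
) -> EdgeTable:
    """Extract every read-supported k−1-overlap edge in one
    map → collate → reduce cycle.

    An edge (a, b) is recorded where valid k-mers occur at adjacent read
    positions and both endpoints are present in ``kmer_table`` (so k-mers
    dropped by the abundance floor take their edges with them); CE is the
    total number of such adjacencies.  Pairs spanning an invalid window
    contribute nothing.
    """
    mode = mode or kmer_table.mode
    if mode != kmer_table.mode:
        raise DataError(
            f"edge extraction mode {mode!r} differs from k-mer table mode "
            f"{kmer_table.mode!r}")
    ds = mode == DOUBLE_STRANDED
    entries = kmer_table.entries
    own = engine is None
    eng = engine or Engine()

    def emit_edges(read: Read):
        wins = valid_kmers(read, k)
        out = []
        prev_pos = -2
        prev_km = ""
        for pos, km in wins:
            if pos == prev_pos + 1:
                a, b = prev_km, km
                if ds:
                    ca, cb = canonical(a), canonical(b)
                    flags = ("F" if ca == a else "R") + ("F" if cb == b else "R")
                    if ca in entries and cb in entries:
                        out.append((f"{ca}\t{cb}".encode(), flags.encode()))
                else:
                    if a in entries and b in entries:
                        out.append((f"{a}\t{b}".encode(), b""))
            prev_pos, prev_km = pos, km
        return out

    def count(key: bytes, values: list[bytes]):
        flags = b",".join(sorted(set(values))) if values[0] else b""
        return [(key, str(len(values)).encode() + b"|" + flags)]

    try:
        kv = eng.map(reads, emit_edges)
        counted = eng.reduce(eng.collate(kv), count)
        edges: dict[tuple[str, str], Edge] = {}
        for key, val in counted.iter_pairs():
            s, t = key.decode().split("\t")
            ce_s, _, flags = val.decode().partition("|")
            orient = frozenset(
                (f[0], f[1]) for f in flags.split(",")) if flags else frozenset()
            edges[(s, t)] = Edge(s, t, int(ce_s), orient)
        counted.close()
    finally:
        if own:
            eng.close()
    logger.info("extracted %d edges (k=%d, %s)", len(edges), k, mode)
    return EdgeTable(edges=edges, k=k)


def filter_edges(edge_table: EdgeTable, rule: str = FILTER_AND) -> EdgeTable:
    """Keep only maximal-abundance edges per node.

    Under the default AND rule an edge survives iff its CE equals the
    maximum CE over its source's out-edges and the maximum over its
    target's in-edges; under OR either maximality suffices.  Ties at a
    maximum are all retained, the operation is idempotent, and an
    unbranched path passes through unchanged.  The node set is untouched.
    """
    if rule not in (FILTER_AND, FILTER_OR):
        raise ValueError(f"unknown filter rule: {rule!r}")
    out_max: dict[str, int] = {}
    in_max: dict[str, int] = {}
    for (s, t), e in edge_table.edges.items():
        if e.ce > out_max.get(s, 0):
            out_max[s] = e.ce
        if e.ce > in_max.get(t, 0):
            in_max[t] = e.ce
    if rule == FILTER_AND:
        kept = {
            pair: e for pair, e in edge_table.edges.items()
            if e.ce == out_max[e.source] and e.ce == in_max[e.target]
        }
    else:
        kept = {
            pair: e for pair, e in edge_table.edges.items()
            if e.ce == out_max[e.source] or e.ce == in_max[e.target]
        }
    logger.info("edge filter (%s rule): %d -> %d edges",
                rule, len(edge_table), len(kept))
    return EdgeTable(edges=kept, k=edge_table.k)
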