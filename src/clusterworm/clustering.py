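"""K-mer clustering: connected components by iterative zone propagation.

Every node starts in its own "zone" (a provisional cluster label, assigned
0..N−1 by lexicographic rank so the labelling is deterministic).  Each
iteration is one map → collate → reduce cycle: zones are exchanged across
edges (both directions — edge direction is ignored, connectivity is
undirected), gathered per node, and each node adopts the minimum of its own
and the received zones.  A zone can therefore grow by one layer of
neighbours per iteration; when an iteration changes nothing, every
connected component carries a single zone — the minimum initial zone in the
component — and the partition is the graph's connected components.

The map step only emits a zone across an edge when it is strictly smaller
than the receiving endpoint's current zone.  Labels that cannot win the
min-reduce are never shipped, which keeps late iterations (where only the
wavefront of each component's minimum is still moving) cheap; the reduced
result, the changed count and the iteration trajectory are identical to
exchanging every zone every time.

Per-node zones are monotonically non-increasing across iterations, and the
zone sum strictly decreases in every non-final iteration, which is the
termination argument; the iteration count is bounded by the graph diameter
plus the one confirming sweep.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

from .engine import Engine
from .errors import ConsistencyError, DataError
from .graph import EdgeTable
from .kmers import KmerTable

logger = logging.getLogger(__name__)

__all__ = [
    "ZoneAssignment",
    "init_zones",
    "propagate_zones_once",
    "find_connected_components",
]

DEFAULT_MAX_ITER = 10_000


@dataclass
class ZoneAssignment:
    """Per-k-mer cluster label Z; at convergence one zone per connected
    component."""

    zone: dict[str, int]
    n_zones: int = 0
    iterations_run: int = 0

    def __len__(self) -> int:
        return len(self.zone)

    def zone_sizes(self) -> dict[int, int]:
        sizes: dict[int, int] = {}
        for z in self.zone.values():
            sizes[z] = sizes.get(z, 0) + 1
        return sizes

    def to_tsv(self, path: str | Path) -> None:
        """Dump as ``kmer<TAB>zone`` sorted by k-mer."""
        with open(path, "wt") as fh:
            fh.write(f"#n_zones={self.n_zones}\titerations={self.iterations_run}\n")
            for kmer in sorted(self.zone):
                fh.write(f"{kmer}\t{self.zone[kmer]}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ZoneAssignment":
        zone: dict[str, int] = {}
        iterations = 0
        with open(path, "rt") as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                if line.startswith("#"):
                    for part in line[1:].split("\t"):
                        key, _, val = part.partition("=")
                        if key == "iterations":
                            iterations = int(val)
                    continue
                try:
                    kmer, z = line.split("\t")
                    zone[kmer] = int(z)
                except ValueError as exc:
                    raise DataError(
                        f"{path}: line {lineno}: bad zone table row") from exc
        return cls(zone=zone, n_zones=len(set(zone.values())),
                   iterations_run=iterations)


def init_zones(kmer_table: KmerTable) -> ZoneAssignment:
    """Assign distinct zones 0..N−1 by lexicographic rank of the k-mers."""
    zone = {kmer: i for i, kmer in enumerate(sorted(kmer_table.entries))}
    return ZoneAssignment(zone=zone, n_zones=len(zone), iterations_run=0)


def propagate_zones_once(
    zones: ZoneAssignment,
    edges: EdgeTable,
    engine: Engine | None = None,
) -> tuple[ZoneAssignment, int]:
    """One zone-exchange sweep; returns the new assignment and the number
    of nodes whose zone decreased.

    Fatal if an edge endpoint has no zone.
    """
    own = engine is None
    eng = engine or Engine()
    zone = zones.zone

    def emit(pair: tuple[str, str]):
        s, t = pair
        try:
            zs, zt = zone[s], zone[t]
        except KeyError as exc:
            raise ConsistencyError(
                f"edge endpoint {exc.args[0]!r} has no zone assignment") from exc
        if zs < zt:
            return [(t.encode(), str(zs).encode())]
        if zt < zs:
            return [(s.encode(), str(zt).encode())]
        return []

    def adopt(key: bytes, values: list[bytes]):
        return [(key, str(min(int(v) for v in values)).encode())]

    try:
        kv = eng.map(edges.edges.keys(), emit)
        reduced = eng.reduce(eng.collate(kv), adopt)
        new_zone = dict(zone)
        changed = 0
        for key, val in reduced.iter_pairs():
            node, z = key.decode(), int(val)
            if z < new_zone[node]:
                new_zone[node] = z
                changed += 1
        reduced.close()
    finally:
        if own:
            eng.close()
    out = ZoneAssignment(
        zone=new_zone,
        n_zones=len(set(new_zone.values())),
        iterations_run=zones.iterations_run + 1,
    )
    return out, changed


def find_connected_components(
    kmer_table: KmerTable,
    edges: EdgeTable,
    engine: Engine | None = None,
    max_iter: int = DEFAULT_MAX_ITER,
) -> ZoneAssignment:
    """Iterate zone propagation to a fixed point.

    At convergence the zone partition equals the connected components of
    the undirected graph; each component's zone is the minimum initial zone
    among its nodes.  Non-convergence within ``max_iter`` is fatal — the
    iteration is monotone and must terminate.
    """
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    own = engine is None
    eng = engine or Engine()
    zones = init_zones(kmer_table)
    try:
        for _ in range(max_iter):
            zones, changed = propagate_zones_once(zones, edges, eng)
            if changed == 0:
                break
        else:
            raise RuntimeError(
                f"zone propagation did not converge within {max_iter} "
                "iterations; this indicates a bug")
    finally:
        if own:
            eng.close()
    sizes = sorted(zones.zone_sizes().values())
    if sizes:
        median = sizes[len(sizes) // 2]
        logger.info(
            "clustering: %d zones over %d k-mers in %d iterations "
            "(cluster sizes min=%d median=%d max=%d)",
            zones.n_zones, len(zones), zones.iterations_run,
            sizes[0], median, sizes[-1])
    return zones
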