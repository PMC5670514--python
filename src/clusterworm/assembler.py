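"""Per-cluster greedy contig assembly (inchworm-style), and the composed
pipeline.

After clustering, k-mers and their abundances are regrouped by zone into
per-cluster hash maps (two collate cycles: first by k-mer to join each node
to its zone and abundance, then by zone to gather each cluster).  Each
cluster is then assembled independently: seed at the highest-abundance
unused k-mer, extend 3′ then 5′ one base at a time by always taking the
overlapping candidate k-mer with the highest abundance, stop when no
candidate exists or the path would revisit a k-mer already placed in the
current contig, then retire every constituent k-mer and repeat.  Because
every candidate must be present in the cluster's own map, extension
implicitly honours the filtered graph topology that defined the cluster.

Tie-breaks are lexicographic (smallest appended base during extension,
smallest k-mer when seeding), making assembly deterministic regardless of
hash-map iteration order, worker count or pagesize.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .clustering import ZoneAssignment, find_connected_components
from .config import PipelineParams
from .engine import Engine, EngineConfig
from .errors import ConsistencyError
from .graph import EdgeTable, extract_edges, filter_edges
from .kmers import (
    DOUBLE_STRANDED,
    KmerTable,
    canonical,
    count_kmers,
    reverse_complement,
)
from .seqio import read_sequences, write_contigs_fasta

logger = logging.getLogger(__name__)

__all__ = [
    "Cluster",
    "Contig",
    "PipelineResult",
    "group_by_zone",
    "extend",
    "assemble_cluster",
    "run_pipeline",
]

THREE_PRIME = "3prime"
FIVE_PRIME = "5prime"


@dataclass
class Cluster:
    """One zone's k-mers with their abundances — the per-cluster hash map
    handed to the greedy assembler."""

    zone: int
    kmer_map: dict[str, int]

    def __len__(self) -> int:
        return len(self.kmer_map)


@dataclass
class Contig:
    """Assembled sequence, the zone it came from, and per-position k-mer
    abundances (length = len(sequence) − k + 1)."""

    sequence: str
    zone: int
    coverage: list[int]

    def __len__(self) -> int:
        return len(self.sequence)


def group_by_zone(
    zones: ZoneAssignment,
    kmer_table: KmerTable,
    engine: Engine | None = None,
) -> list[Cluster]:
    """Partition the k-mer table into per-zone clusters via two collate
    cycles (k-mer join, then zone gather), returning clusters sorted by
    zone ID.  The union of the cluster maps is exactly the k-mer table.

    Fatal if any k-mer is missing its zone or its abundance.
    """
    own = engine is None
    eng = engine or Engine()

    def tag(item: tuple[str, str, int]):
        kind, kmer, value = item
        return [(kmer.encode(), f"{kind}{value}".encode())]

    def join(key: bytes, values: list[bytes]):
        zone = abund = None
        for v in values:
            if v[:1] == b"Z":
                zone = v[1:]
            else:
                abund = v[1:]
        if zone is None:
            raise ConsistencyError(f"k-mer {key.decode()!r} has no zone")
        if abund is None:
            raise ConsistencyError(f"k-mer {key.decode()!r} has no abundance")
        return [(zone, key + b":" + abund)]

    items = itertools.chain(
        (("C", kmer, count) for kmer, count in kmer_table.entries.items()),
        (("Z", kmer, z) for kmer, z in zones.zone.items()),
    )
    try:
        joined = eng.reduce(eng.collate(eng.map(items, tag)), join)
        by_zone = eng.collate(joined)
        clusters: list[Cluster] = []
        for zkey, values in by_zone.iter_groups():
            kmer_map: dict[str, int] = {}
            for v in values:
                kmer, _, abund = v.decode().rpartition(":")
                kmer_map[kmer] = int(abund)
            clusters.append(Cluster(zone=int(zkey), kmer_map=kmer_map))
        by_zone.close()
    finally:
        if own:
            eng.close()
    clusters.sort(key=lambda c: c.zone)
    return clusters


def _best_candidate(
    core: str,
    prepend: bool,
    kmer_map: Mapping[str, int],
    ds: bool,
) -> tuple[str, str] | None:
    """Highest-abundance candidate k-mer extending ``core`` by one base
    (tie → lexicographically smallest base).  Returns (lookup key, base)."""
    best_key = best_base = None
    best_c = -1
    for base in "ACGT":
        cand = base + core if prepend else core + base
        key = canonical(cand) if ds else cand
        c = kmer_map.get(key)
        if c is not None and c > best_c:
            best_key, best_base, best_c = key, base, c
    if best_key is None:
        return None
    return best_key, best_base


def extend(
    seed_or_contig: str,
    kmer_map: Mapping[str, int],
    direction: str,
    k: int,
    used: set | None = None,
    mode: str | None = None,
) -> str:
    """Greedily extend a sequence one base at a time in the given direction.

    At each step the candidate k-mers are the ≤4 one-base shifts of the
    terminal k-mer; the one present in ``kmer_map`` with the highest
    abundance wins (tie → lexicographically smallest new base).  Extension
    stops when no candidate is present, or when the chosen candidate was
    already placed during this contig's growth (loop guard — so a
    self-loop or cycle is traversed at most once).

    ``used`` carries the contig-local guard set across the 3′ and 5′ calls;
    in double-stranded mode lookups are by canonical form.
    """
    if direction not in (THREE_PRIME, FIVE_PRIME):
        raise ValueError(f"unknown direction: {direction!r}")
    if used is None:
        used = set()
    ds = mode == DOUBLE_STRANDED
    seq = seed_or_contig
    prepend = direction == FIVE_PRIME
    while True:
        core = (seq[:k - 1] if prepend else seq[len(seq) - k + 1:]) if k > 1 else ""
        found = _best_candidate(core, prepend, kmer_map, ds)
        if found is None:
            return seq
        key, base = found
        if key in used:
            return seq
        used.add(key)
        seq = base + seq if prepend else seq + base


def assemble_cluster(
    cluster: Cluster,
    k: int,
    min_contig_length: int = 48,
    mode: str | None = None,
) -> list[Contig]:
    """Greedy contig construction over one cluster's k-mer map.

    Repeatedly seed at the unused k-mer with the highest abundance (tie →
    lexicographically smallest), extend 3′ then 5′ through unused k-mers,
    retire every constituent k-mer, and report the contig if it reaches
    ``min_contig_length``.  Every k-mer is consumed by exactly one contig
    attempt, so contigs within a cluster never share k-mers.
    """
    ds = mode == DOUBLE_STRANDED
    unused = dict(cluster.kmer_map)
    seed_order = sorted(cluster.kmer_map, key=lambda km: (-cluster.kmer_map[km], km))
    contigs: list[Contig] = []
    for seed in seed_order:
        if seed not in unused:
            continue
        local_used: set = set()
        seq = extend(seed, unused, THREE_PRIME, k, used=local_used, mode=mode)
        seq = extend(seq, unused, FIVE_PRIME, k, used=local_used, mode=mode)
        coverage: list[int] = []
        for i in range(len(seq) - k + 1):
            km = seq[i:i + k]
            key = canonical(km) if ds else km
            coverage.append(cluster.kmer_map[key])
            unused.pop(key, None)
        if len(seq) >= min_contig_length:
            contigs.append(Contig(sequence=seq, zone=cluster.zone, coverage=coverage))
    return contigs


@dataclass
class PipelineResult:
    """Contigs plus the per-step counters the pipeline logs."""

    contigs: list[Contig]
    kmer_table: KmerTable
    zones: ZoneAssignment
    counters: dict[str, int]


def run_pipeline(
    reads_path: str | Path,
    params: PipelineParams | None = None,
    out_fasta: str | Path | None = None,
) -> PipelineResult:
    """Run the full pipeline: count k-mers, extract and filter edges,
    cluster by connected components, regroup by zone, assemble each
    cluster, and optionally write the merged contig FASTA.

    Contigs are ordered by zone then assembly order, so the output is
    byte-identical across worker counts and pagesizes.
    """
    params = params or PipelineParams()
    cfg = EngineConfig(
        n_workers=params.n_workers,
        pagesize=params.pagesize,
        spill_dir=params.spill_dir,
        seed=params.seed,
        keep_temp=params.keep_temp,
    )
    with Engine(cfg) as eng:
        kmer_table = count_kmers(
            read_sequences(reads_path), params.k, mode=params.mode,
            min_kmer_cov=params.min_kmer_cov, engine=eng)
        edge_table = extract_edges(
            read_sequences(reads_path), params.k, kmer_table, engine=eng)
        filtered = filter_edges(edge_table, rule=params.filter_rule)
        zones = find_connected_components(kmer_table, filtered, engine=eng)
        clusters = group_by_zone(zones, kmer_table, engine=eng)
        contigs: list[Contig] = []
        for cluster in clusters:
            contigs.extend(
                assemble_cluster(cluster, params.k,
                                 min_contig_length=params.min_contig_length,
                                 mode=params.mode))
        counters = {
            "unique_kmers": len(kmer_table),
            "edges_raw": len(edge_table),
            "edges_filtered": len(filtered),
            "zones": zones.n_zones,
            "cluster_iterations": zones.iterations_run,
            "contigs": len(contigs),
            **eng.counters.as_dict(),
        }
    logger.info("pipeline counters: %s", counters)
    if out_fasta is not None:
        write_contigs_fasta(contigs, out_fasta)
    return PipelineResult(contigs=contigs, kmer_table=kmer_table,
                          zones=zones, counters=counters)
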