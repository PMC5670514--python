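"""Zone regrouping, greedy extension, per-cluster assembly, full pipeline."""

import random

import networkx as nx
import pytest

from clusterworm.assembler import (
    Cluster,
    assemble_cluster,
    extend,
    group_by_zone,
    run_pipeline,
)
from clusterworm.clustering import ZoneAssignment, find_connected_components
from clusterworm.config import PipelineParams
from clusterworm.errors import ConsistencyError
from clusterworm.fixtures import (
    generate_transcripts,
    tile_reads,
    write_reads_fastq,
)
from clusterworm.graph import extract_edges, filter_edges
from clusterworm.kmers import DOUBLE_STRANDED, KmerTable, count_kmers
from clusterworm.seqio import read_sequences


class TestGroupByZone:
    def test_partitions_table_by_zone(self, make_engine):
        table = KmerTable({"AA": 3, "AC": 1, "CC": 2, "GG": 5, "GT": 1}, k=2)
        zones = ZoneAssignment(
            zone={"AA": 0, "AC": 0, "CC": 0, "GG": 3, "GT": 3}, n_zones=2)
        clusters = group_by_zone(zones, table, make_engine(n_workers=3))
        assert [c.zone for c in clusters] == [0, 3]
        assert clusters[0].kmer_map == {"AA": 3, "AC": 1, "CC": 2}
        assert clusters[1].kmer_map == {"GG": 5, "GT": 1}
        assert sum(len(c) for c in clusters) == len(table)

    def test_single_zone_reproduces_table(self, make_engine):
        table = KmerTable({"AA": 1, "CC": 2}, k=2)
        zones = ZoneAssignment(zone={"AA": 0, "CC": 0}, n_zones=1)
        (cluster,) = group_by_zone(zones, table, make_engine())
        assert cluster.kmer_map == table.entries

    def test_missing_zone_fatal(self, make_engine):
        table = KmerTable({"AA": 1, "CC": 2}, k=2)
        zones = ZoneAssignment(zone={"AA": 0}, n_zones=1)
        with pytest.raises(ConsistencyError, match="no zone"):
            group_by_zone(zones, table, make_engine())

    def test_memberships_match_component_oracle(self, make_engine):
        rng = random.Random(55)
        nodes = sorted({"".join(rng.choice("ACGT") for _ in range(6))
                        for _ in range(500)})
        table = KmerTable({n: rng.randrange(1, 9) for n in nodes}, k=6)
        pairs = [(rng.choice(nodes), rng.choice(nodes)) for _ in range(300)]
        from clusterworm.graph import Edge, EdgeTable
        edges = EdgeTable(edges={(s, t): Edge(s, t, 1) for s, t in pairs}, k=6)
        zones = find_connected_components(table, edges, make_engine())
        clusters = group_by_zone(zones, table, make_engine(n_workers=4))
        got = sorted(frozenset(c.kmer_map) for c in clusters)
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(pairs)
        assert got == sorted(frozenset(c) for c in nx.connected_components(g))


class TestExtend:
    KMAP = {"ACG": 10, "CGT": 8, "GTT": 5, "GTA": 2}

    def test_picks_highest_abundance_candidate(self):
        assert extend("ACG", self.KMAP, "3prime", 3) == "ACGTT"

    def test_no_candidates_returns_unchanged(self):
        assert extend("GTT", self.KMAP, "3prime", 3) == "GTT"

    def test_five_prime_prepends(self):
        assert extend("CGT", {"ACG": 4, "CGT": 1}, "5prime", 3) == "ACGT"

    def test_self_loop_guard_traverses_once(self):
        assert extend("AAA", {"AAA": 9}, "3prime", 3) == "AAAA"

    def test_tie_broken_to_lexicographically_smallest_base(self):
        assert extend("ACG", {"ACG": 1, "CGA": 5, "CGT": 5}, "3prime", 3) == "ACGA"

    def test_matches_exhaustive_best_path_on_unbranched_chain(self):
        seq = "ACGTTGCAAT"
        k = 4
        kmap = {seq[i:i + k]: 5 for i in range(len(seq) - k + 1)}
        assert extend(seq[:k], kmap, "3prime", k) == seq
        assert extend(seq[-k:], kmap, "5prime", k) == seq

    def test_rejects_unknown_direction(self):
        with pytest.raises(ValueError):
            extend("ACG", self.KMAP, "sideways", 3)


class TestAssembleCluster:
    def test_greedy_two_contigs(self):
        cluster = Cluster(zone=0, kmer_map=dict(TestExtend.KMAP))
        contigs = assemble_cluster(cluster, 3, min_contig_length=3)
        assert [(c.sequence, c.coverage) for c in contigs] == [
            ("ACGTT", [10, 8, 5]), ("GTA", [2])]

    def test_single_kmer_cluster(self):
        (c,) = assemble_cluster(Cluster(0, {"ACGTA": 7}), 5, min_contig_length=5)
        assert c.sequence == "ACGTA" and c.coverage == [7]

    def test_min_length_suppresses_short_contigs(self):
        cluster = Cluster(zone=0, kmer_map=dict(TestExtend.KMAP))
        contigs = assemble_cluster(cluster, 3, min_contig_length=4)
        assert [c.sequence for c in contigs] == ["ACGTT"]

    def test_unbranched_chain_reconstructed_exactly(self):
        rng = random.Random(2)
        k = 5
        seq = "".join(rng.choice("ACGT") for _ in range(34))  # 30 k-mers
        kmap = {seq[i:i + k]: rng.randrange(1, 50)
                for i in range(len(seq) - k + 1)}
        assert len(kmap) == 30
        (contig,) = assemble_cluster(Cluster(1, kmap), k, min_contig_length=k)
        assert contig.sequence == seq
        assert contig.coverage == [kmap[seq[i:i + k]] for i in range(30)]

    def test_every_kmer_consumed_exactly_once(self):
        rng = random.Random(6)
        kmap = {"".join(rng.choice("ACGT") for _ in range(4)): rng.randrange(1, 9)
                for _ in range(60)}
        contigs = assemble_cluster(Cluster(0, kmap), 4, min_contig_length=1)
        seen = []
        for c in contigs:
            seen.extend(c.sequence[i:i + 4] for i in range(len(c.sequence) - 3))
        assert set(seen) <= set(kmap)
        # duplicates only from the one-pass loop guard within a contig
        assert len(set(seen)) == len(kmap) or len(seen) >= len(kmap)

    def test_invariant_to_kmer_map_insertion_order(self):
        rng = random.Random(12)
        items = [("".join(rng.choice("ACGT") for _ in range(4)),
                  rng.randrange(1, 9)) for _ in range(40)]
        kmap = dict(items)
        base = [(c.sequence, c.coverage)
                for c in assemble_cluster(Cluster(0, kmap), 4, 1)]
        rng.shuffle(items)
        shuffled = dict(items)
        assert [(c.sequence, c.coverage)
                for c in assemble_cluster(Cluster(0, shuffled), 4, 1)] == base


class TestRunPipeline:
    def _write(self, tmp_path, reads):
        p = tmp_path / "reads.fq"
        write_reads_fastq(reads, p)
        return p

    def test_single_transcript_recovered_exactly(self, tmp_path):
        (t,) = generate_transcripts(1, 100, k=25, seed=3)
        p = self._write(tmp_path, tile_reads([t], 50))
        res = run_pipeline(p, PipelineParams(k=25))
        assert res.counters["zones"] == 1
        assert [c.sequence for c in res.contigs] == [t]

    def test_disjoint_transcripts_get_disjoint_zones(self, tmp_path):
        ts = generate_transcripts(2, 120, k=25, seed=4)
        p = self._write(tmp_path, tile_reads(ts, 60))
        res = run_pipeline(p, PipelineParams(k=25))
        assert res.counters["zones"] == 2
        assert sorted(c.sequence for c in res.contigs) == sorted(ts)
        zones = {c.sequence: c.zone for c in res.contigs}
        assert len(set(zones.values())) == 2

    def test_empty_read_file(self, tmp_path):
        p = tmp_path / "empty.fq"
        p.write_text("")
        out = tmp_path / "c.fa"
        res = run_pipeline(p, PipelineParams(), out_fasta=out)
        assert res.contigs == []
        assert res.counters["unique_kmers"] == 0
        assert out.read_text() == ""

    def test_double_stranded_mode_recovers_up_to_orientation(self, tmp_path):
        from clusterworm.kmers import reverse_complement
        (t,) = generate_transcripts(1, 90, k=21, seed=9)
        reads = tile_reads([t], 45)
        # flip alternate reads to the other strand
        flipped = [
            r if i % 2 == 0 else
            type(r)(r.id, reverse_complement(r.sequence))
            for i, r in enumerate(reads)
        ]
        p = self._write(tmp_path, flipped)
        res = run_pipeline(p, PipelineParams(k=21, mode=DOUBLE_STRANDED,
                                             min_contig_length=48))
        assert res.counters["zones"] == 1
        (c,) = res.contigs
        assert c.sequence in (t, reverse_complement(t))
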