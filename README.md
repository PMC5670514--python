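# clusterworm

De novo transcriptome assembly from RNA-Seq reads begins with a de Bruijn
graph: nodes are the unique k-mers of the read set, edges are k−1
suffix-to-prefix overlaps. Holding that whole graph in one shared-memory
hash table is what drives the notoriously large RAM footprint of greedy
k-mer assemblers. `clusterworm` takes the alternative route: it first
*partitions* the graph into connected components ("zones", each a proxy for
one gene's transcript variants) using only streaming map/collate/reduce
passes over key/value data, and then runs a greedy inchworm-style contig
builder independently inside each small component. Because every stage is
expressed over hash-partitioned key/value stores with out-of-core spilling,
no step ever needs the whole graph in memory.

It is aimed at people building or studying assembly pipelines: the engine,
every intermediate table, and every stage are importable and inspectable.

## The method

For reads *R* and k-mer size *k* (default 25):

1. **Count** — one map/collate/reduce cycle turns *R* into the node table
   *V* = {k-mer → abundance *C*} (canonicalised to min(s, revcomp(s)) in
   double-stranded mode; windows containing N are skipped; nodes with
   *C* < `min_kmer_cov` are dropped).
2. **Edges** — a second cycle extracts the edge table
   *E* = {(a, b) → abundance *CE*}, where (a, b) are valid k-mers at
   *adjacent* read positions and *CE* counts those co-occurrences. Only
   read-supported overlaps become edges; no trial extensions are made.
3. **Filter** — an edge survives only if its *CE* is maximal among its
   source's outgoing (3′) edges **and** among its target's incoming (5′)
   edges (ties all retained). This removes low-abundance branches —
   typically sequencing-error spurs — and keeps component sizes balanced.
4. **Cluster** — every node starts in its own zone *Z* (0..N−1 by
   lexicographic rank); each map/collate/reduce iteration ships zone labels
   across edges and lets every node adopt the minimum of its own and its
   neighbours' zones. At the fixed point each connected component carries a
   single zone — its minimum initial label.
5. **Assemble** — k-mers and abundances are regrouped by zone into
   per-cluster hash maps; within each cluster, seed at the most abundant
   unused k-mer, extend 3′ then 5′ by always taking the overlapping k-mer
   with the highest abundance *C* (lexicographic tie-breaks, a loop guard
   against repeated k-mers), retire the constituent k-mers, repeat.

The final FASTA is byte-identical for any number of logical workers and any
pagesize: partitioning and paging change only *where* data sits, never the
result.

## Worked example

```bash
clusterworm simulate --n-transcripts 3 --length 200 --read-length 80 \
    --tile --seed 4                # writes transcripts.fa + reads.fq
clusterworm run --reads reads.fq --k 25 --out contigs.fa
```

prints (log on stderr, summary on stdout):

```
INFO clusterworm.kmers: counted 528 unique k-mers (k=25, strand_specific, min_cov=1)
INFO clusterworm.graph: extracted 525 edges (k=25, strand_specific)
INFO clusterworm.graph: edge filter (and rule): 525 -> 525 edges
INFO clusterworm.clustering: clustering: 3 zones over 528 k-mers in 170 iterations (cluster sizes min=176 median=176 max=176)
wrote 3 contigs from 3 clusters to contigs.fa
```

Read it as: 3 transcripts of 200 nt yield 3 × 176 = 528 unique 25-mers and
525 read-supported overlap edges (176 nodes, 175 edges per transcript —
unbranched chains, so the filter removes nothing). Clustering finds exactly
3 zones, and each cluster assembles into one contig:

```
>cluster0_contig0 len=200 cov=38.50
CGATTCAAATGACGGCAGCAGGCCGGGAGTCC...
```

`len` is the contig length and `cov` the mean abundance of its constituent
k-mers; with exhaustive error-free tiling each contig reproduces its
transcript character-for-character.

The stages can also be run separately with TSV handoffs
(`count` → `edges` → `cluster` → `assemble`), producing byte-identical
output; `--help` on any subcommand lists the knobs (`--mode ss|ds`,
`--min-kmer-cov`, `--filter-rule and|or`, `--n-workers`, `--pagesize`, …).

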