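# Methods

## Model and assumptions

`clusterworm` treats de novo transcriptome assembly as two decoupled
problems: *partitioning* the de Bruijn graph of a read set into connected
components, and *greedy path reconstruction* within each component. The
underlying assumptions are the usual ones for greedy k-mer assembly:

- k is large enough (default 25) that k-mers are effectively unique to one
  transcript locus, so connected components approximate genes;
- sequencing errors create low-abundance k-mers and low-abundance branch
  edges, so abundance-maximal extension follows the true sequence;
- coverage is deep enough that every adjacent k-mer pair of a transcript is
  witnessed by at least one read (edges are only created from *observed*
  adjacencies, never by trying all four possible extensions).

Every stage is phrased as map → collate → reduce over hash-partitioned
key/value stores. This buys two properties: the memory high-water mark is
bounded by `pagesize` per partition (overflow pages spill to disk and are
transparently merged back), and the final output provably cannot depend on
the partitioning — which the test suite checks at the byte level.

## Pipeline stages and their contracts

1. **k-mer counting.** Map emits one `(k-mer, ε)` pair per valid window
   (windows containing a non-ACGT base are skipped entirely; reads shorter
   than k are counted and skipped); collate groups occurrences; reduce
   counts them and applies the `min_kmer_cov` floor. In double-stranded
   mode the map canonicalises each window first, which makes counting a
   read and counting its reverse complement identical by construction.
2. **Edge extraction.** Map emits `(a⊕b, ε)` for every pair of valid
   k-mers at adjacent read positions whose endpoints both survived
   counting; the reduce gives the edge abundance CE. CE is defined as the
   adjacency occurrence count — the pair analogue of node abundance. A
   k-mer dropped by the abundance floor takes its incident edges with it.
3. **Edge filtering.** An edge survives iff CE equals both the source's
   out-maximum and the target's in-maximum (AND rule); ties at a maximum
   are all kept. The AND rule was chosen over OR because it splits
   clusters most aggressively while always preserving each node's best
   edge, which is exactly what keeps component sizes balanced; the OR
   variant is available (`--filter-rule or`) for comparison. The known
   cost, accepted and documented: AND can delete a node's only out-edge
   when that edge loses at its target. The filter is idempotent and is the
   identity on branch-free paths.
4. **Clustering.** Zones are initialised 0..N−1 by lexicographic k-mer
   rank (deterministic and platform-independent). Each iteration is one
   engine cycle: zones travel across edges in both directions (direction
   is ignored — connectivity is undirected), are collated per node, and
   each node adopts the minimum of its own and the received zones; the
   numerically smaller zone always wins, making the result independent of
   edge order. Convergence is `changed = 0` after a full sweep, i.e. one
   confirming iteration; per-node zones are non-increasing and their sum
   strictly decreases every non-final iteration, which is the termination
   argument. The iteration count is bounded by the largest component
   diameter + 1, so plain layer propagation (rather than an accelerated
   pointer-jumping scheme) is acceptable at the problem sizes targeted
   here; transcript-path components of a few hundred nodes cost a few
   hundred cheap iterations. As an optimisation, the map step only ships a
   zone across an edge when it is strictly smaller than the receiving
   endpoint's current zone — values that cannot win the min-reduce are
   never emitted — which leaves the reduced result, the changed count and
   the trajectory exactly equal to the full-emission form while making
   late iterations (only the wavefronts still moving) nearly free.
5. **Per-cluster assembly.** Two further collate cycles join each k-mer to
   its zone and abundance and then gather each zone's k-mer → abundance
   hash map. Greedy construction follows node abundance C, not edge
   abundance CE: candidates are restricted to the cluster's own map, which
   already reflects the filtered topology. Seeding takes the most abundant
   unused k-mer; extension appends the most abundant overlapping candidate
   one base at a time. All ties break lexicographically (smallest k-mer
   when seeding, smallest appended base when extending) purely so that
   assembly is a deterministic function of the cluster content. A
   contig-local guard stops extension when the chosen candidate was
   already placed during the current contig's growth (so a perfect repeat
   or cycle is traversed at most once), and constituent k-mers are retired
   globally so each k-mer is consumed by exactly one contig attempt.
   Contigs shorter than `min_contig_length` (default 48 nt, the
   conventional minimum reported contig size) are suppressed.

## Engine numerics and determinism

- Key ownership: `crc32(key) mod n_workers` (IEEE CRC-32 as in
  `zlib.crc32`) — fixed, published, seed-independent, identical across
  platforms. Bitwise compatibility with any particular MPI MapReduce
  implementation is not attempted.
- Workers are logical partitions processed sequentially; a concurrent
  backend would have to preserve the per-partition output contract.
- Spill format: length-prefixed binary records, one file per overflowed
  page, deleted on success (`keep_temp` retains them). Collate on a
  spilled partition external-sorts page-sized runs and streams a heap
  merge; in-memory partitions use plain hash-map grouping. The two paths
  are checked against each other in the tests.
- Value order inside a KMV group is unspecified; every reducer in the
  pipeline is order-insensitive (counting, min, set union).
- Degenerate inputs: empty read files produce empty tables and an empty
  FASTA with a warning, not an error; `k = 1` and single-k-mer clusters
  are handled (a homopolymer read yields a self-loop edge that the loop
  guard traverses once).

## Synthetic data

The generator emulates the situation the pipeline is designed for:
transcripts as uniform-random ACGT strings, optionally regenerated until
no k-mer repeats within or is shared between transcripts (rejection
sampling with an up-front feasibility check on the expected birthday
collision load). Reads are either sampled at uniform random starts to a
target mean coverage or, in tiling mode, emitted at every start position a
fixed number of times; substitution errors are i.i.d. per base. Default
study conditions used by the acceptance script: 20 transcripts × 300 nt,
k = 25, 100 nt reads, exhaustive tiling (4,020 reads ≈ 100× interior
coverage), and a noisy variant at 0.5% substitution error assembled with
`min_kmer_cov = 2` — sized so the whole study runs in seconds on one core
while still forcing multi-page spilling under small pagesizes.

What this does *not* emulate, and what passing therefore does not show:
real transcriptomes share k-mers across paralogs and isoforms (components
are then not 1:1 with genes), coverage is non-uniform, errors include
indels, and paired-end structure carries information this stage ignores
(mates are deliberately consumed as independent reads). The tests
demonstrate correctness of the machinery — counting, graph construction,
clustering, deterministic greedy assembly, engine transparency — not
biological assembly quality on real data.

## Design choices that were genuinely open

- How the two endpoint maximality tests combine in the filter (AND
  default, OR behind a flag) — discussed above.
- CE as occurrence count of the adjacent pair, mirroring node-abundance
  semantics, rather than any read-pair-aware weighting.
- Extension ranks candidates by node abundance C; edges serve clustering
  only.
- The loop guard allows the chosen candidate to be appended once before a
  revisit stops extension, so a homopolymer seed `AAA` grows to `AAAA`
  rather than stalling immediately.
- `run` streams the input file directly; `split` (round-robin by record
  index, never by byte offset) exists for multi-file workflows, since hash
  partitioning makes a pre-split redundant in a single-process run.

## Known limitations

- Pure-Python throughput: tens of thousands of reads per second, suitable
  for methodological work, not production assembly of 10⁸-read libraries.
- Plain min-label propagation needs O(diameter) iterations; components
  with very long unbranched paths dominate clustering time.
- Double-stranded mode reports each contig in its seed's orientation; no
  attempt is made to orient contigs consistently across a cluster.
- No MPI or multi-process backend; fault tolerance and Hadoop-style
  shuffles are out of scope.
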