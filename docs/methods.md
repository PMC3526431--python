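# Methods

## The tiled iterative assembly model

`tigerasm` assembles paired-end short reads by decomposing the problem into
*read tiles* — subsets of read pairs that are assembled completely
independently — and refining the decomposition iteratively.  The premise is
that a de Bruijn graph (DBG) assembler working on only the reads of one
genomic region sees none of the *ambiguous k-mers* contributed by the rest
of the genome, so it needs far less memory and produces cleaner contigs.
The difficulty is that the right read-to-region assignment is only known
once the genome is assembled; the framework therefore bootstraps:

1. **Random tiling.** Read pairs are partitioned randomly and evenly into N
   tiles (sizes differ by at most one pair; mates stay together).
2. **Per-tile assembly.** Each tile is assembled by the embedded assembler.
   The merged contigs across tiles form the *intermediate reference
   genome*.  An optional extra assembly pass treats the merged contigs
   themselves as long error-free reads and joins contigs that overlap by at
   least the elongation k-mer size.
3. **Contig clustering.** Contigs of the intermediate reference are grouped
   into C clusters of mutually overlapping contigs (details below), each
   cluster ideally covering one contiguous genomic region.
4. **Read clustering.** Every input read is aligned against every contig
   cluster; a pair joins the tile of each cluster that either mate matches
   (*mate rescue*).  A pair may sit in several tiles when similar contigs
   ended up in different clusters; a pair is never collected twice for the
   same tile.
5. **Re-assembly** of the new tiles, merge, optional elongation.
6. Steps 3–5 repeat for a fixed, user-chosen number of iterations.

Each cycle transfers information both ways: better contigs produce better
read clusters, and better-clustered reads produce longer, cleaner contigs.
Two entry modes exist: **R** starts from the random tiling; **I** starts
from an existing assembly, entering the loop directly at step 3.

## Embedded assembler

The built-in reference assembler is a conventional canonical-k-mer DBG:

* **Canonical k-mers, odd k.** A k-mer and its reverse complement are one
  node; odd k forbids self-reverse-complement k-mers.
* **Coverage cutoff** (default 2): k-mers seen fewer times are dropped.
  This exists solely to shed sequencing-error k-mers — on error-free input
  (such as the standard synthetic conditions) the correct setting is 1,
  since every discarded k-mer would be genuine sequence.
* **Tip clipping**: dead-end paths shorter than 2k bp attached at exactly
  one end are removed iteratively.
* **Bubble popping with a coverage-ratio gate.** Two paths joining the same
  entry and exit nodes with near-equal length form a simple bubble.  The
  lower-coverage path is removed only when its mean coverage is below half
  the keeper's.  An ungated popper also deletes *balanced* bubbles, which
  are genuine near-identical sequence (diverged repeat copies, haplotypes)
  rather than errors; deleting them measurably removed repeat copies from
  assemblies of the standard synthetic genome.
* **Contigs** are maximal non-branching paths of at least `min_contig`
  (default 200 bp).

Any other assembler can be plugged in through the assembler contract
(a pure function `(reads, k, params) -> (contigs, used_read_count)`); an
adapter template for external command-line assemblers is provided but not
exercised by the test suite.

### Auto-k selection

For each tile and round, candidate odd k values are drawn from a range
(default 21–61 for ~100 bp reads; the upper end is what practitioners use
for high-coverage, low-error data and is needed to span the divergent sites
of interspersed repeats).  Each candidate assembly is scored by

    composite = (used_reads / tile_reads) * total_contig_length * sqrt(N50)

which rewards read usage and total length before contiguity, so a high-N50
but low-coverage contig set never wins.  The best k per tile is remembered
and re-tried alongside fresh candidates in later rounds; ties prefer
smaller k.

### Merged-set elongation and the skip heuristic

The elongation pass re-assembles the merged contig set at a large k
(largest odd value ≤ min(96, shortest contig − 1), coverage cutoff 1, no
tip clipping).  Its result replaces the merged set only when it is
*better*; because raw total length would reward duplicated sequence, the
acceptance score counts **distinct** k-mers instead of base pairs:

    score = distinct_kmers * sqrt(N50)

with an equal score accepted only when the contig count drops (pure
deduplication).  Once an elongation fails to improve, it is skipped in all
later iterations — it mostly pays off while contigs are still short.

## Contig clustering

Overlap between contigs is estimated by shared fixed-length *words*, not by
alignment.  Words (default w = 32, stride 4) are sampled from the canonical
orientation of each contig — with a stride > 1 the sampling grid must not
depend on which strand a contig was assembled on — and canonicalized
individually.  An inverted file (word → contigs) accumulates, per contig
pair, the number of shared words; that count is the edge weight of the
contig connectivity graph, and vertex weights are contig lengths.  Words
occurring in more than `max_postings` contigs (default 50) are skipped
during accumulation: they stem from high-copy repeats and would create
quadratically many low-information edges.  The exact-intersection oracle in
the tests disables this cap.

The graph is partitioned into C clusters by an internal multilevel
partitioner: heavy-edge-matching coarsening, then a component-aware
region-growing initial assignment (one seed per connected component,
largest first; extra seeds at BFS-farthest vertices; the lightest cluster
repeatedly absorbs the unassigned vertex it connects to most strongly), and
Kernighan–Lin-style boundary refinement during uncoarsening.  Balance uses
scaled vertex weights 1 + length/vertex_scale (default scale 1000), so
clusters balance mostly by contig count and only softly by length — the
partition stays edge-driven, and contigs with no connectivity at all are
dealt round-robin in decreasing length order.  A plain-text graph dump and
assignment reader allow substituting a dedicated external partitioner.

Region growing replaced a heaviest-vertex-first greedy seeding after the
latter was observed to strand zero-gain "islands" in chain-shaped graphs
(the typical shape for contigs tiling a chromosome) that local refinement
cannot dissolve.

## Read clustering

The internal aligner is seed-and-verify: every canonical seed-length
substring (default 20 bp, stride 1) of a cluster's contigs is indexed; a
read is looked up by its first, middle and last seeds, and each candidate
placement is verified end-to-end with at most `max_mismatch` (default 2)
substitutions.  With reads at least three seed-lengths long and a mismatch
budget below three, at least one seed is always intact, so the aligner is
exactly equivalent to a full placement scan (the test suite asserts this
against a brute-force oracle).  Gapped alignment is out of scope: the data
model upstream is substitution-only.

Collection rules: a pair joins every cluster either mate matches; both
mates always travel together.  Two guards handle repeats:

* **Multiplicity cap.** A pair hitting more than half of all clusters is
  kept only in one: the cluster supported by its most *specific* mate (the
  mate hitting the fewest clusters), preferring clusters both mates hit,
  then fewest mismatches.  Without the specificity rule, repeat-spanning
  pairs — exactly the pairs that let a flank extend into its repeat copy —
  were dumped into an arbitrary cluster.
* **Rescue tiles.** Pairs aligning to no cluster are gathered into
  dedicated extra tiles (randomly split, each at most the average tile
  size).  Concentrating them lets genome regions absent from the
  intermediate reference re-nucleate contigs at full local coverage;
  spreading them across all tiles (the obvious alternative) dilutes their
  coverage by 1/C and measurably stalls convergence.

## Evaluation metrics

N50 is the length of the contig at which the largest-first cumulative sum
reaches half the assembly; NG50 uses half the *reference genome* instead
and is 0 when even the whole assembly falls short.  Contigs shorter than
200 bp are discarded before any metric.

The contig-to-reference evaluator targets synthetic, substitution-dominated
data: 50 bp anchors that occur exactly once in the reference (counting both
strands) are chained into collinear blocks (same chromosome, strand and
diagonal); blocks continue across anchor-free stretches on the same
diagonal, with substitution columns counted as SNPs by direct comparison.
Junctions between blocks are classified as indels (same chromosome/strand,
diagonal shift = indel length, both gaps ≤ 1 kb) or misjoins (anything
else).  Terminal blocks are extended base-by-base along their diagonal
while the sequence matches exactly — unique anchors cannot exist inside
repeats, so a contig ending inside a repeat copy would otherwise lose a
perfectly matching tail.  The error-corrected NG50 splits every contig at
each misjoin and at each indel strictly longer than 5 bp (a 5 bp indel does
not split; 6 bp does) and recomputes NG50 over the fragments.  Genome
coverage is the fraction of reference bases under at least one block;
duplication is the excess depth (sum of depth−1 over covered bases) as a
percentage of the genome.

Known limitation: contigs consisting purely of repeat-shared sequence have
no unique anchors and count as unaligned, so a few hundred bases per
collapsed repeat copy can register as uncovered even when an exactly
matching contig exists.  A production evaluation of real genomes should use
a dedicated whole-genome aligner; this evaluator is deliberately
self-contained and deterministic for synthetic references.

## Synthetic data

The generator produces a uniform-random haploid genome (one or more
chromosomes), plants interspersed repeat families (copies mutated from a
family consensus at a per-base divergence, placed uniformly without
overlap), and samples FR paired-end reads: fragment length Normal(mean, sd)
truncated to [2·read_length, chromosome]; uniform start; either strand with
probability 1/2; i.i.d. substitution errors.  Quality scores, indels, GC
bias, PCR duplicates and mate-pair (RF) libraries are not modelled.  Every
read carries an exact truth location, and with error rate 0 every read is a
perfect genome substring — this is what makes brute-force oracles exact.

Passing tests on this generator therefore demonstrate the *mechanics* of
the method (tiling, clustering, iteration, metrics) under idealized reads;
they do not demonstrate robustness to indel errors, coverage bias, or
biological repeat structure beyond the planted family model.

## Standard study conditions

The fixture exercised by the acceptance tests and the reproduction script:
100 kb single-chromosome genome; one repeat family, five 500 bp copies at
1% divergence; 30× error-free 100 bp read pairs, insert 300 ± 30 bp;
N = C = 8 tiles; 3 refinement iterations; coverage cutoff 1 (error-free
input); auto-k over 21–61 with 3 candidates per tile per round.  At this
scale a full run takes a few minutes on one CPU core.  Expected behaviour:
the first merged assembly already reaches ≈ 98% genome coverage with NG50
in the tens of kilobases; iterations close random coverage gaps (final
coverage ≥ 99%) and never degrade NG50; duplication grows by a few percent
because independently assembled tiles overlap — the known cost of tiled
assembly, normally removed by a downstream scaffolder, which is out of
scope here.

## Numerical and determinism notes

* Every random choice (genome, reads, tiling, k-candidate sampling,
  coarsening order, rescue-tile split) derives from one user seed plus the
  iteration and tile indices; runs are pure functions of (reads, config),
  reproducible across checkpoint/resume and serial vs. parallel execution
  (worker results are gathered in tile order; tiles share no state).
* Tie-breaks are explicit everywhere: smaller k on equal composite score;
  lexicographic k-mer/sequence order in the DBG walk and bubble popping;
  lowest cluster index in read collection; sorted ids in the partitioner.
* Degenerate inputs: an empty read tile or a tile whose reads are all
  shorter than k assembles to an empty contig set (not an error); an empty
  merged set falls back to the previous intermediate reference, and if the
  reference is empty the pipeline re-tiles randomly for one round.
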