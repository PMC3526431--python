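"""Read tiling, the built-in assembler, the auto-k composite score and
merged-set elongation."""

import hashlib

import pytest

from tigerasm import dbg
from tigerasm._dna import revcomp
from tigerasm.fixtures import tiling_read_pairs
from tigerasm.seq_io import Contig, ContigSet, Read
from tigerasm.simulate import simulate_genome
from tigerasm.tile_assembly import (
    AssemblyScore,
    ConfigurationError,
    KmerHistory,
    assemble_tile,
    elongate_merged_detailed,
    partition_reads_random,
    score_assembly,
    select_kmers,
)


def make_pairs(n, length=30):
    reads = []
    for i in range(n):
        reads.append(Read(f"r{i}/1", "ACGT" * (length // 4), f"r{i}", 1))
        reads.append(Read(f"r{i}/2", "TTGG" * (length // 4), f"r{i}", 2))
    return reads


class TestPartition:
    def test_single_tile_takes_everything(self):
        tiles = partition_reads_random(make_pairs(10), 1, seed=0)
        assert len(tiles) == 1
        assert len(tiles[0].members) == 10

    def test_even_split_sizes(self):
        tiles = partition_reads_random(make_pairs(10), 3, seed=0)
        assert sorted(len(t.members) for t in tiles) == [3, 3, 4]

    def test_disjoint_and_conserving(self):
        reads = make_pairs(101)
        tiles = partition_reads_random(reads, 7, seed=3)
        seen = [pid for t in tiles for pid in t.members]
        assert len(seen) == len(set(seen)) == 101
        assert max(len(t.members) for t in tiles) - min(len(t.members) for t in tiles) <= 1

    def test_deterministic_per_seed(self):
        reads = make_pairs(1000)
        def digest(tiles):
            return hashlib.sha256(
                "|".join(",".join(t.members) for t in tiles).encode()
            ).hexdigest()
        a = digest(partition_reads_random(reads, 150, seed=9))
        b = digest(partition_reads_random(reads, 150, seed=9))
        c = digest(partition_reads_random(reads, 150, seed=10))
        assert a == b
        assert a != c

    def test_more_tiles_than_pairs_raises(self):
        with pytest.raises(ConfigurationError):
            partition_reads_random(make_pairs(3), 5, seed=0)


class TestBuiltinAssembler:
    def test_reconstructs_nonrepetitive_region(self):
        genome, _ = simulate_genome(5_000, 1, None, seed=13)
        reads = tiling_read_pairs(genome, read_length=50, coverage=20.0)
        contigs, used = assemble_tile(reads, 31, min_contig=200, coverage_cutoff=1)
        assert len(contigs) == 1
        g = genome[0].sequence
        assert contigs[0].sequence in (g, revcomp(g))
        assert used == len(reads)

    def test_empty_reads_give_empty_set(self):
        contigs, used = assemble_tile([], 31)
        assert len(contigs) == 0 and used == 0

    def test_reads_shorter_than_k_give_empty_set(self):
        reads = make_pairs(5, length=20)
        contigs, used = assemble_tile(reads, 31)
        assert len(contigs) == 0 and used == 0

    def test_two_disjoint_regions_give_two_contigs(self):
        genome, _ = simulate_genome(10_000, 1, None, seed=14)
        g = genome[0].sequence
        region1 = ContigSet([Contig("a", g[:2000])])
        region2 = ContigSet([Contig("b", g[5000:7000])])
        reads = tiling_read_pairs(region1, 50, 20.0) + [
            Read(r.id + "x", r.sequence, r.pair_id + "x", r.mate_index)
            for r in tiling_read_pairs(region2, 50, 20.0)
        ]
        contigs, _ = assemble_tile(reads, 31, min_contig=200, coverage_cutoff=1)
        assert len(contigs) == 2
        recovered = sorted(c.sequence if c.sequence[0] != "T" else c.sequence for c in contigs)
        canon = {min(c.sequence, revcomp(c.sequence)) for c in contigs}
        expected = {min(g[:2000], revcomp(g[:2000])), min(g[5000:7000], revcomp(g[5000:7000]))}
        assert canon == expected

    def test_even_k_rejected(self):
        with pytest.raises(ValueError):
            dbg.assemble(["ACGTACGTACGT"], 4)

    def test_every_contig_is_spelled_by_the_kmer_graph(self):
        genome, _ = simulate_genome(3_000, 1, None, seed=15)
        reads = tiling_read_pairs(genome, 50, 10.0)
        k = 21
        contigs, _ = dbg.assemble(reads, k, min_contig=100, coverage_cutoff=1)
        table = dbg.count_kmers([r.sequence for r in reads], k)
        for c in contigs:
            for i in range(len(c.sequence) - k + 1):
                km = c.sequence[i : i + k]
                assert min(km, revcomp(km)) in table

    def test_memory_surrogate_tiles_bound_single_assembly(self):
        genome, _ = simulate_genome(10_000, 1, None, seed=16)
        reads = tiling_read_pairs(genome, 50, 20.0)
        tiles = partition_reads_random(reads, 4, seed=1)
        from tigerasm.seq_io import pair_up

        pairs = pair_up(reads)
        whole = dbg.distinct_kmer_count([r.sequence for r in reads], 31)
        per_tile = [
            dbg.distinct_kmer_count([r.sequence for r in t.reads(pairs)], 31)
            for t in tiles
        ]
        assert max(per_tile) <= whole

    def test_determinism(self):
        genome, _ = simulate_genome(3_000, 1, None, seed=17)
        reads = tiling_read_pairs(genome, 50, 15.0)
        a, _ = dbg.assemble(reads, 25, coverage_cutoff=1)
        b, _ = dbg.assemble(reads, 25, coverage_cutoff=1)
        assert [c.sequence for c in a] == [c.sequence for c in b]


class TestScore:
    def test_empty_contigs_score_zero(self):
        score, comp = score_assembly(ContigSet([]), 0, 100)
        assert comp == 0.0
        assert score == AssemblyScore(0, 0, 0)

    def test_monotonic_in_n50(self):
        a = ContigSet([Contig("a", "A" * 9000)])
        b = ContigSet([Contig("b1", "A" * 4000), Contig("b2", "C" * 4000), Contig("b3", "G" * 1000)])
        # equal usage and near-equal total length; higher n50 must win
        _, ca = score_assembly(a, 80, 100)
        _, cb = score_assembly(b, 80, 100)
        assert ca > cb

    def test_usage_dominates_contiguity(self):
        # high-coverage/low-N50 candidate must beat low-coverage/high-N50 one
        a = ContigSet([Contig(f"a{i}", "A" * 4000) for i in range(22)] + [Contig("at", "C" * 2000)])
        b = ContigSet([Contig("b0", "A" * 16000), Contig("b1", "C" * 14000)])
        _, ca = score_assembly(a, 90, 100)   # usage 0.9, total 90 kb, n50 4 kb
        _, cb = score_assembly(b, 30, 100)   # usage 0.3, total 30 kb, n50 16 kb
        assert ca > cb

    def test_used_cannot_exceed_total(self):
        with pytest.raises(ValueError):
            score_assembly(ContigSet([]), 10, 5)


class TestSelectKmers:
    def test_empty_history_samples_distinct_odds_in_range(self):
        ks = select_kmers(KmerHistory(), (21, 31), 3, seed=5)
        assert len(ks) == len(set(ks)) == 3
        assert all(21 <= k <= 31 and k % 2 == 1 for k in ks)

    def test_best_k_always_retained(self):
        hist = KmerHistory()
        hist.record(25, AssemblyScore(90, 10_000, 900), 1e6)
        hist.record(29, AssemblyScore(50, 8_000, 500), 5e5)
        ks = select_kmers(hist, (21, 31), 3, seed=1)
        assert ks[0] == 25

    def test_exhausted_range_returns_all_available(self):
        assert select_kmers(KmerHistory(), (31, 31), 3, seed=0) == [31]

    def test_deterministic_per_seed(self):
        assert select_kmers(KmerHistory(), (21, 61), 4, seed=2) == select_kmers(
            KmerHistory(), (21, 61), 4, seed=2
        )

    def test_even_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            select_kmers(KmerHistory(), (20, 30), 3, seed=0)


class TestElongation:
    def test_overlapping_contigs_are_joined(self):
        genome, _ = simulate_genome(3_000, 1, None, seed=19)
        g = genome[0].sequence
        merged = ContigSet([Contig("a", g[:1600]), Contig("b", g[1400:3000])])
        res = elongate_merged_detailed(merged, min_contig=200)
        assert res.improved
        assert len(res.contigs) == 1
        assert res.contigs[0].sequence in (g, revcomp(g))

    def test_disjoint_contigs_returned_unchanged(self):
        genome, _ = simulate_genome(3_000, 1, None, seed=20)
        g = genome[0].sequence
        merged = ContigSet([Contig("a", g[:1000]), Contig("b", g[1500:2500])])
        res = elongate_merged_detailed(merged, min_contig=200)
        assert not res.improved
        assert res.contigs is merged

    def test_exact_duplicates_are_collapsed(self):
        genome, _ = simulate_genome(3_000, 1, None, seed=21)
        g = genome[0].sequence
        merged = ContigSet([Contig("a", g[:1200]), Contig("b", g[:1200])])
        res = elongate_merged_detailed(merged, min_contig=200)
        assert res.improved
        assert len(res.contigs) == 1
        assert res.contigs[0].sequence in (g[:1200], revcomp(g[:1200]))

    def test_all_contigs_shorter_than_k_long_is_a_noop(self):
        merged = ContigSet([Contig("a", "ACGTACGTAC")])
        res = elongate_merged_detailed(merged, k_long=31)
        assert res.contigs is merged and not res.improved
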