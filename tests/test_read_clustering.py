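"""Seed-and-verify aligner vs. a brute-force placement oracle, and the
read-collection rules (once per cluster, mate rescue, unplaced pool)."""

import numpy as np
import pytest

from tigerasm._dna import revcomp
from tigerasm.contig_clustering import ContigClusterSet
from tigerasm.read_clustering import (
    align_read,
    brute_force_align,
    build_read_aligner,
    cluster_reads,
)
from tigerasm.seq_io import Contig, ContigSet, Read
from tigerasm.simulate import simulate_genome


def _read(seq, rid="r/1", pid="r", mate=1):
    return Read(rid, seq, pid, mate)


@pytest.fixture(scope="module")
def contig_set():
    genome, _ = simulate_genome(5_000, 1, None, seed=51)
    g = genome[0].sequence
    return ContigSet(
        [Contig(f"c{i}", g[i * 450 : i * 450 + 600]) for i in range(10)]
    )


class TestIndex:
    def test_indexed_position_count(self):
        cs = ContigSet([Contig("c", "ACGTACGTACGTACGTACGTACGTA")])  # length 25
        aligner = build_read_aligner(cs, seed_length=20)
        assert sum(len(v) for v in aligner.index.values()) == 25 - 20 + 1

    def test_exact_query_hits_position_zero(self, contig_set):
        aligner = build_read_aligner(contig_set, 20)
        read = _read(contig_set[0].sequence[:60])
        hits = align_read(read, aligner, max_mismatch=0)
        assert any(h.contig_id == "c0" and h.position == 0 and h.strand == "+" for h in hits)

    def test_reverse_complement_query_hits_minus_strand(self, contig_set):
        aligner = build_read_aligner(contig_set, 20)
        read = _read(revcomp(contig_set[3].sequence[100:160]))
        hits = align_read(read, aligner, max_mismatch=0)
        assert any(h.contig_id == "c3" and h.position == 100 and h.strand == "-" for h in hits)

    def test_empty_contig_set_aligns_nothing(self):
        aligner = build_read_aligner(ContigSet([]), 20)
        assert align_read(_read("ACGT" * 20), aligner) == []


class TestAlignRead:
    def test_mismatch_threshold_edge(self, contig_set):
        aligner = build_read_aligner(contig_set, 20)
        base = contig_set[0].sequence[200:280]
        mutated = list(base)
        for pos in (25, 45, 65):  # 3 substitutions > max_mismatch 2
            mutated[pos] = "A" if mutated[pos] != "A" else "C"
        hits = align_read(_read("".join(mutated)), aligner, max_mismatch=2)
        assert all(not (h.contig_id == "c0" and h.position == 200) for h in hits)
        two = list(base)
        for pos in (25, 45):
            two[pos] = "A" if two[pos] != "A" else "C"
        hits = align_read(_read("".join(two)), aligner, max_mismatch=2)
        assert any(h.contig_id == "c0" and h.position == 200 and h.mismatches == 2 for h in hits)

    def test_error_free_reads_all_hit_truth_position(self, contig_set):
        aligner = build_read_aligner(contig_set, 20)
        rng = np.random.default_rng(52)
        for _ in range(200):
            ci = int(rng.integers(0, len(contig_set)))
            start = int(rng.integers(0, contig_set[ci].length - 80))
            seq = contig_set[ci].sequence[start : start + 80]
            hits = align_read(_read(seq), aligner, max_mismatch=2)
            assert any(h.contig_id == f"c{ci}" and h.position == start for h in hits)

    def test_equals_brute_force_oracle(self, contig_set):
        """Full equivalence with the exhaustive placement scan (reads at
        least 3x the seed length, mismatch budget below the seed count, so
        one of the three seeds is always intact)."""
        aligner = build_read_aligner(contig_set, 20)
        rng = np.random.default_rng(53)
        genome, _ = simulate_genome(5_000, 1, None, seed=51)
        g = genome[0].sequence
        for i in range(100):
            start = int(rng.integers(0, len(g) - 70))
            seq = list(g[start : start + 70])
            for _ in range(int(rng.integers(0, 3))):
                p = int(rng.integers(0, 70))
                seq[p] = "ACGT"[int(rng.integers(0, 4))]
            if rng.random() < 0.5:
                seq = list(revcomp("".join(seq)))
            read = _read("".join(seq), rid=f"q{i}/1", pid=f"q{i}")
            fast = sorted(
                (h.contig_id, h.position, h.strand, h.mismatches)
                for h in align_read(read, aligner, max_mismatch=2)
            )
            slow = sorted(
                (h.contig_id, h.position, h.strand, h.mismatches)
                for h in brute_force_align(read, contig_set, max_mismatch=2)
            )
            assert fast == slow, read.id


class TestClusterReads:
    def _clusters(self, *groups):
        clusters = [list(g) for g in groups]
        assignment = {cid: i for i, g in enumerate(clusters) for cid in g}
        return ContigClusterSet(clusters=clusters, assignment=assignment)

    def _fixture(self):
        genome, _ = simulate_genome(6_000, 1, None, seed=54)
        g = genome[0].sequence
        contigs = ContigSet(
            [
                Contig("a", g[:1500]),
                Contig("b", g[2000:3500]),
                Contig("dup1", g[4000:5000]),
                Contig("dup2", g[4000:5000]),  # same sequence in another cluster
            ]
        )
        clusters = self._clusters(["a"], ["b"], ["dup1"], ["dup2"])
        return g, contigs, clusters

    def test_mate_rescue_collects_both_mates(self):
        g, contigs, clusters = self._fixture()
        # mate 1 from contig b's region; mate 2 from an uncovered region
        reads = [
            Read("p/1", g[2100:2200], "p", 1),
            Read("p/2", revcomp(g[5500:5600]), "p", 2),
        ]
        result = cluster_reads(reads, clusters, contigs, multiplicity_cap=False)
        assert result.membership["p"] == {1}
        assert result.tiles[1].members == ["p"]
        assert all("p" not in t.members for t in result.tiles if t.index != 1)

    def test_duplicated_contig_collects_pair_in_both_clusters(self):
        g, contigs, clusters = self._fixture()
        reads = [
            Read("q/1", g[4200:4300], "q", 1),
            Read("q/2", revcomp(g[4400:4500]), "q", 2),
        ]
        result = cluster_reads(reads, clusters, contigs, multiplicity_cap=False)
        assert result.membership["q"] == {2, 3}

    def test_unmatched_pair_goes_to_unplaced_pool(self):
        g, contigs, clusters = self._fixture()
        reads = [
            Read("u/1", g[5500:5600], "u", 1),
            Read("u/2", revcomp(g[5700:5800]), "u", 2),
        ]
        result = cluster_reads(reads, clusters, contigs, multiplicity_cap=False)
        assert result.unplaced == ["u"]
        assert all(not t.members for t in result.tiles)

    def test_tiles_contain_whole_pairs_and_conserve_reads(self):
        g, contigs, clusters = self._fixture()
        rng = np.random.default_rng(55)
        reads = []
        for i in range(60):
            start = int(rng.integers(0, len(g) - 400))
            reads.append(Read(f"m{i}/1", g[start : start + 100], f"m{i}", 1))
            reads.append(
                Read(f"m{i}/2", revcomp(g[start + 200 : start + 300]), f"m{i}", 2)
            )
        result = cluster_reads(reads, clusters, contigs, multiplicity_cap=False)
        placed = set(result.membership)
        assert placed | set(result.unplaced) == {f"m{i}" for i in range(60)}
        assert placed.isdisjoint(result.unplaced)
        for tile in result.tiles:
            assert len(tile.members) == len(set(tile.members))

    def test_multiplicity_cap_keeps_best_cluster_only(self):
        g, _, _ = self._fixture()
        seg = g[100:1100]
        contigs = ContigSet([Contig(f"r{i}", seg) for i in range(4)])
        clusters = self._clusters(["r0"], ["r1"], ["r2"], ["r3"])
        reads = [
            Read("w/1", seg[100:200], "w", 1),
            Read("w/2", revcomp(seg[300:400]), "w", 2),
        ]
        capped = cluster_reads(reads, clusters, contigs, multiplicity_cap=True)
        assert capped.membership["w"] == {0}
        uncapped = cluster_reads(reads, clusters, contigs, multiplicity_cap=False)
        assert uncapped.membership["w"] == {0, 1, 2, 3}
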