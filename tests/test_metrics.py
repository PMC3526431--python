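"""N50/NG50 against brute force, and the exact-anchor evaluator on
constructed fixtures with known misjoins, indels and duplications."""

import itertools

import pytest

from tigerasm._dna import revcomp
from tigerasm.metrics import (
    align_contigs_to_reference,
    corrected_ng50,
    coverage_and_duplication,
    evaluate,
    n50,
    ng50,
)
from tigerasm.seq_io import Contig, ContigSet
from tigerasm.simulate import simulate_genome


def brute_force_n50(lengths):
    """Independent definition: the length of the contig at which the
    largest-first cumulative sum first reaches half the assembly — found by
    scanning every candidate threshold L and keeping the largest L whose
    suffix sum reaches the half-way mark."""
    total = sum(lengths)
    if total == 0:
        return 0
    satisfying = [
        L for L in set(lengths) if sum(x for x in lengths if x >= L) >= total / 2
    ]
    return max(satisfying)


def brute_force_ng50(lengths, genome_size):
    satisfying = [
        L
        for L in set(lengths)
        if sum(x for x in lengths if x >= L) >= genome_size / 2
    ]
    return max(satisfying) if satisfying else 0


class TestN50Definitions:
    def test_singleton(self):
        assert n50([10]) == 10

    def test_worked_example(self):
        # total 12, half 6; descending cumulative 5, 9 -> second contig
        assert n50([5, 4, 3]) == 4

    def test_empty(self):
        assert n50([]) == 0

    def test_ng50_worked_example(self):
        assert ng50([5, 4, 3], 10) == 5

    def test_ng50_whole_genome_contig(self):
        assert ng50([1234], 1234) == 1234

    def test_ng50_unreachable_half_genome(self):
        assert ng50([3, 3], 100) == 0

    def test_all_subsets_of_1_to_8_match_brute_force(self):
        universe = list(range(1, 9))
        for r in range(1, len(universe) + 1):
            for combo in itertools.combinations(universe, r):
                lengths = list(combo)
                assert n50(lengths) == brute_force_n50(lengths), lengths
                for gs in (1, sum(lengths) // 2 or 1, sum(lengths), sum(lengths) * 2):
                    assert ng50(lengths, gs) == brute_force_ng50(lengths, gs), (
                        lengths,
                        gs,
                    )

    def test_multisets_match_brute_force(self):
        for lengths in ([2, 2, 2], [1, 1, 8, 8], [5, 5, 5, 1], [7, 7]):
            assert n50(lengths) == brute_force_n50(lengths)
            assert ng50(lengths, sum(lengths)) == brute_force_ng50(lengths, sum(lengths))


@pytest.fixture(scope="module")
def reference():
    genome, _ = simulate_genome(20_000, 2, None, seed=21)
    return genome


class TestAnchorEvaluator:
    def test_exact_substring_is_one_clean_block(self, reference):
        chrom = reference[0]
        contigs = ContigSet([Contig("c", chrom.sequence[1000:4000])])
        (aln,) = align_contigs_to_reference(contigs, reference)
        assert aln.aligned
        assert aln.breakpoints == []
        assert aln.snps == 0
        assert aln.chromosome == chrom.id
        assert aln.ref_interval == (1000, 4000)
        assert aln.strand == "+"

    def test_reverse_complement_contig_aligns_minus(self, reference):
        chrom = reference[0]
        contigs = ContigSet([Contig("c", revcomp(chrom.sequence[1000:4000]))])
        (aln,) = align_contigs_to_reference(contigs, reference)
        assert aln.aligned and aln.strand == "-"
        assert aln.ref_interval == (1000, 4000)

    def test_interchromosomal_junction_is_one_misjoin(self, reference):
        a = reference[0].sequence[2000:4000]
        b = reference[1].sequence[5000:7000]
        contigs = ContigSet([Contig("chimera", a + b)])
        (aln,) = align_contigs_to_reference(contigs, reference)
        misjoins = [bp for bp in aln.breakpoints if bp.kind == "misjoin"]
        assert len(misjoins) == 1
        # the junction may slide a couple of bases when the flanking
        # sequences happen to agree across it
        assert abs(misjoins[0].position - 2000) <= 5

    def test_deletion_is_one_indel_of_that_length(self, reference):
        s = reference[0].sequence[1000:5000]
        contig = s[:2000] + s[2007:]  # 7 bp deletion
        (aln,) = align_contigs_to_reference(ContigSet([Contig("d", contig)]), reference)
        indels = [bp for bp in aln.breakpoints if bp.kind == "indel"]
        assert len(indels) == 1
        assert indels[0].indel_length == 7

    def test_isolated_substitution_counts_as_snp_not_breakpoint(self, reference):
        s = list(reference[0].sequence[1000:4000])
        s[1500] = "A" if s[1500] != "A" else "C"
        (aln,) = align_contigs_to_reference(ContigSet([Contig("s", "".join(s))]), reference)
        assert aln.breakpoints == []
        assert aln.snps == 1

    def test_unanchored_contig_reported_unaligned(self, reference):
        (aln,) = align_contigs_to_reference(
            ContigSet([Contig("junk", "ACGT" * 100)]), reference
        )
        assert not aln.aligned


class TestCorrectedNG50:
    def _chimera_alignment(self, reference, split_at=4000, total=10_000):
        a = reference[0].sequence[:split_at]
        b = reference[1].sequence[: total - split_at]
        contigs = ContigSet([Contig("x", a + b)])
        return align_contigs_to_reference(contigs, reference)

    def test_no_breakpoints_equals_ng50(self, reference):
        contigs = ContigSet([Contig("c", reference[0].sequence[:8000])])
        aln = align_contigs_to_reference(contigs, reference)
        gs = reference.total_length
        assert corrected_ng50(aln, gs) == ng50([8000], gs)

    def test_misjoin_splits_contig(self, reference):
        aln = self._chimera_alignment(reference, split_at=4000, total=10_000)
        # fragments ~4000 + ~6000 against a 10 kb half-genome target of 5 kb:
        # the 6 kb fragment alone crosses it (junction may slide a few bases)
        assert abs(corrected_ng50(aln, 10_000) - 6000) <= 5

    def test_five_bp_indel_does_not_split_six_bp_does(self, reference):
        s = reference[0].sequence[:9000]
        for gap, expect_split in ((5, False), (6, True)):
            contig = s[:4000] + s[4000 + gap :]
            aln = align_contigs_to_reference(
                ContigSet([Contig("i", contig)]), reference
            )
            frags = aln[0].fragment_lengths(indel_split_threshold=5)
            if expect_split:
                assert sorted(frags) == [4000, 5000 - gap]
            else:
                assert frags == [9000 - gap]

    def test_corrected_never_exceeds_ng50_and_conserves_length(self, reference):
        aln = self._chimera_alignment(reference)
        gs = reference.total_length
        for a in aln:
            assert sum(a.fragment_lengths()) == a.contig_length
        assert corrected_ng50(aln, gs) <= ng50([a.contig_length for a in aln], gs)


class TestCoverageDuplication:
    def test_perfect_single_copy(self, reference):
        contigs = ContigSet(
            [Contig(c.id + "_copy", c.sequence) for c in reference]
        )
        aln = align_contigs_to_reference(contigs, reference)
        cov, unal, dup = coverage_and_duplication(aln, reference)
        assert cov == pytest.approx(100.0)
        assert unal == pytest.approx(0.0)
        assert dup == pytest.approx(0.0)

    def test_extra_copy_of_segment_counts_as_duplication(self, reference):
        chrom = reference[0]
        contigs = ContigSet(
            [
                Contig(c.id + "_copy", c.sequence)
                for c in reference
            ]
            + [Contig("extra", chrom.sequence[2000:4000])]
        )
        aln = align_contigs_to_reference(contigs, reference)
        cov, unal, dup = coverage_and_duplication(aln, reference)
        assert cov == pytest.approx(100.0)
        # one extra 2 kb copy over a 20 kb genome
        assert dup == pytest.approx(10.0)

    def test_empty_assembly(self, reference):
        cov, unal, dup = coverage_and_duplication([], reference)
        assert (cov, unal, dup) == (0.0, 100.0, 0.0)

    def test_coverage_plus_unaligned_is_exactly_100(self, reference):
        contigs = ContigSet([Contig("c", reference[0].sequence[3000:9000])])
        aln = align_contigs_to_reference(contigs, reference)
        cov, unal, _ = coverage_and_duplication(aln, reference)
        assert cov + unal == pytest.approx(100.0)


class TestEvaluate:
    def test_minimum_contig_filter_applied_first(self, reference):
        contigs = ContigSet(
            [
                Contig("long", reference[0].sequence[:5000]),
                Contig("short", reference[0].sequence[6000:6150]),  # < 200 bp
            ]
        )
        report = evaluate(contigs, reference, min_contig=200)
        assert report.contig_count == 1
        assert report.n50 == 5000
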