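"""Standard synthetic study conditions used by the test suite and the
reproduction script.

The *standard fixture* is a desk-scale stand-in for a bacterial-style
assembly problem: a 100 kb haploid single-chromosome genome carrying one
interspersed repeat family (five 500 bp copies at 1% divergence — enough to
create ambiguous k-mers without making the genome unassemblable), sequenced
at 30-fold coverage with error-free 100 bp paired reads from a 300 +/- 30 bp
fragment library, tiled into N = C = 8 tiles for 3 refinement iterations.

Because the reads carry no sequencing errors, the assembler's k-mer
coverage cutoff is set to 1 here: a cutoff above 1 exists solely to shed
error k-mers and would otherwise discard genuine low-coverage k-mers in the
thinly covered initial random tiles.
"""

from __future__ import annotations

from ._dna import revcomp
from .pipeline import TigerConfig
from .seq_io import Contig, ContigSet, Read
from .simulate import (
    ReadSimParams,
    RepeatSpec,
    simulate_genome,
    simulate_paired_reads,
)

STANDARD_GENOME_LENGTH = 100_000
STANDARD_REPEATS = RepeatSpec(
    family_count=1, unit_length=500, copies_per_family=5, divergence=0.01
)
STANDARD_READ_PARAMS = dict(
    read_length=100, coverage=30.0, insert_mean=300.0, insert_sd=30.0, error_rate=0.0
)


def standard_fixture(seed: int = 7, threads: int = 1):
    """(genome, repeat truth, reads, read truth, config) for the standard
    synthetic study conditions."""
    genome, repeat_truth = simulate_genome(
        STANDARD_GENOME_LENGTH, chromosomes=1, repeats=STANDARD_REPEATS, seed=seed
    )
    params = ReadSimParams(seed=seed + 1, **STANDARD_READ_PARAMS)
    reads, read_truth = simulate_paired_reads(genome, params)
    config = TigerConfig(
        mode="R",
        n_tiles=8,
        n_clusters=8,
        iterations=3,
        k_min=21,
        k_max=61,
        n_candidates=3,
        seed=seed,
        coverage_cutoff=1,  # error-free reads: nothing to filter
        threads=threads,
    )
    return genome, repeat_truth, reads, read_truth, config


def tiling_read_pairs(
    genome: ContigSet, read_length: int = 100, coverage: float = 30.0
) -> list[Read]:
    """Deterministic evenly spaced read pairs tiling each chromosome end to
    end (no randomness, no errors): start positions step by
    read_length/coverage and the final read is pinned to the chromosome end,
    so every base — including the termini — is covered."""
    reads: list[Read] = []
    pair_no = 0
    step = max(1, int(round(read_length / coverage)))
    for chrom in genome:
        seq = chrom.sequence
        starts = list(range(0, len(seq) - read_length + 1, step))
        if starts[-1] != len(seq) - read_length:
            starts.append(len(seq) - read_length)
        for s in starts:
            fwd = seq[s : s + read_length]
            reads.append(
                Read(
                    id=f"tile{pair_no}/1",
                    sequence=fwd,
                    pair_id=f"tile{pair_no}",
                    mate_index=1,
                )
            )
            reads.append(
                Read(
                    id=f"tile{pair_no}/2",
                    sequence=revcomp(fwd),
                    pair_id=f"tile{pair_no}",
                    mate_index=2,
                )
            )
            pair_no += 1
    return reads


def chopped_contigs(
    genome: ContigSet, window: int = 2000, overlap: int = 500
) -> tuple[ContigSet, dict[str, str]]:
    """Chop each chromosome into overlapping windows — synthetic 'contigs'
    with known chromosome-of-origin labels, for clustering-purity checks."""
    contigs: list[Contig] = []
    labels: dict[str, str] = {}
    i = 0
    step = window - overlap
    for chrom in genome:
        seq = chrom.sequence
        pos = 0
        while pos < len(seq):
            piece = seq[pos : pos + window]
            if len(piece) < window // 2 and contigs:
                break  # fold a trailing sliver into the previous window's span
            cid = f"frag{i}"
            contigs.append(Contig(id=cid, sequence=piece))
            labels[cid] = chrom.id
            i += 1
            pos += step
    return ContigSet(contigs=contigs, label="chopped"), labels
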