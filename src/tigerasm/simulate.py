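"""Synthetic genomes and paired-end read sets with exact ground truth.

The generator emulates the input class the assembler targets: a haploid DNA
genome with interspersed repeat families, sequenced as uniform-coverage
paired-end short reads (Illumina-style fragment libraries, FR orientation)
with i.i.d. per-base substitution errors.  Indels, quality scores, GC bias
and PCR duplicates are deliberately not modelled: substitution-only reads
keep every truth interval an exact genome substring, so downstream oracles
can compare assembled sequence to truth base-for-base.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from ._dna import revcomp
from .seq_io import Contig, ContigSet

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SizingError(ValueError):
    """Requested simulation geometry cannot fit (repeats, read length...)."""


@dataclass(frozen=True)
class RepeatSpec:
    """An interspersed repeat structure: ``family_count`` families, each with
    ``copies_per_family`` copies of a ``unit_length``-bp unit, copies mutated
    away from the family consensus at per-base probability ``divergence``."""

    family_count: int
    unit_length: int
    copies_per_family: int
    divergence: float

    def __post_init__(self) -> None:
        if self.unit_length < 1 or self.copies_per_family < 1 or self.family_count < 1:
            raise ValueError("repeat family geometry must be >= 1")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")


@dataclass(frozen=True)
class ReadSimParams:
    """Paired-end library parameters.

    coverage is fold-coverage of the genome by read bases; insert_mean/sd
    describe the full fragment length (outer distance); error_rate is the
    per-base substitution probability.
    """

    read_length: int
    coverage: float
    insert_mean: float
    insert_sd: float
    error_rate: float
    seed: int

    def __post_init__(self) -> None:
        if self.insert_mean < 2 * self.read_length:
            raise ValueError("insert_mean must be >= 2 * read_length")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0, 1)")


class RepeatPlacement(NamedTuple):
    family: int
    copy: int
    chromosome: str
    start: int
    end: int  # half-open


class ReadTruth(NamedTuple):
    chromosome: str
    start: int  # 0-based start of the read on the forward reference strand
    strand: str  # '+' or '-'


def _random_seq(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    """Substitute each base independently with probability ``rate`` (always to
    a different base)."""
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = _BASES[_BASES != out[i]]
        out[i] = choices[rng.integers(0, 3)]
    return out


def simulate_genome(
    length: int,
    chromosomes: int = 1,
    repeats: RepeatSpec | None = None,
    seed: int = 0,
) -> tuple[ContigSet, list[RepeatPlacement]]:
    """Generate a random haploid genome with optional interspersed repeats.

    Total length is split as evenly as possible across chromosomes.  Repeat
    copies (all families and copies together) are placed at non-overlapping
    uniformly drawn positions and recorded in the returned truth list.
    Deterministic for a fixed seed.
    """
    if length < chromosomes * 1000:
        raise SizingError("genome length must be >= 1 kb per chromosome")
    rng = np.random.default_rng(seed)
    base = length // chromosomes
    sizes = [base + (1 if i < length % chromosomes else 0) for i in range(chromosomes)]
    chrom_arrays = [_random_seq(rng, n) for n in sizes]
    placements: list[RepeatPlacement] = []

    if repeats is not None:
        total_copies = repeats.family_count * repeats.copies_per_family
        if repeats.unit_length * total_copies > length // 2:
            raise SizingError("repeat copies occupy more than half the genome")
        units = [
            _random_seq(rng, repeats.unit_length) for _ in range(repeats.family_count)
        ]
        # Occupied intervals per chromosome, to keep placements disjoint.
        occupied: list[list[tuple[int, int]]] = [[] for _ in range(chromosomes)]
        for fam in range(repeats.family_count):
            for cp in range(repeats.copies_per_family):
                placed = False
                for _ in range(1000):
                    ci = int(rng.integers(0, chromosomes))
                    if sizes[ci] < repeats.unit_length:
                        continue
                    start = int(rng.integers(0, sizes[ci] - repeats.unit_length + 1))
                    end = start + repeats.unit_length
                    if any(s < end and start < e for s, e in occupied[ci]):
                        continue
                    copy_seq = _mutate(rng, units[fam], repeats.divergence)
                    chrom_arrays[ci][start:end] = copy_seq
                    occupied[ci].append((start, end))
                    placements.append(
                        RepeatPlacement(fam, cp, f"chr{ci + 1}", start, end)
                    )
                    placed = True
                    break
                if not placed:
                    raise SizingError(
                        "could not place repeat copies without overlap; "
                        "genome too small for the requested repeat structure"
                    )
    contigs = [
        Contig(id=f"chr{i + 1}", sequence=arr.tobytes().decode())
        for i, arr in enumerate(chrom_arrays)
    ]
    return ContigSet(contigs=contigs, label="simulated-genome"), placements


def simulate_paired_reads(
    genome: ContigSet, params: ReadSimParams
) -> tuple[list["Read"], dict[str, ReadTruth]]:
    """Simulate FR paired-end reads from ``genome``.

    The number of pairs is coverage * genome_length / (2 * read_length),
    rounded.  Each fragment's length is Normal(insert_mean, insert_sd)
    truncated to [2*read_length, chromosome length]; the start is uniform;
    the fragment samples either genome strand with probability 1/2.  Mate 1
    is the first ``read_length`` bases of the fragment, mate 2 the reverse
    complement of the last ``read_length`` bases.  Truth positions are on
    the forward reference strand.
    """
    from .seq_io import Read  # local import to avoid cycle at module load

    if len(genome) == 0:
        raise ValueError("genome is empty")
    rl = params.read_length
    shortest = min(c.length for c in genome)
    if rl > shortest:
        raise SizingError("read_length exceeds the shortest chromosome")

    rng = np.random.default_rng(params.seed)
    glen = genome.total_length
    n_pairs = int(round(params.coverage * glen / (2 * rl)))
    chrom_seqs = [c.sequence for c in genome]
    chrom_ids = [c.id for c in genome]
    lengths = np.array([c.length for c in genome], dtype=float)
    probs = lengths / lengths.sum()

    chrom_idx = rng.choice(len(genome), size=n_pairs, p=probs)
    frag_lens = rng.normal(params.insert_mean, params.insert_sd, size=n_pairs)
    flip = rng.random(n_pairs) < 0.5

    reads: list[Read] = []
    truth: dict[str, ReadTruth] = {}
    for i in range(n_pairs):
        ci = int(chrom_idx[i])
        chrom = chrom_seqs[ci]
        clen = len(chrom)
        flen = int(round(frag_lens[i]))
        flen = max(2 * rl, min(flen, clen))
        start = int(rng.integers(0, clen - flen + 1))
        frag = chrom[start : start + flen]
        if flip[i]:
            frag = revcomp(frag)
        m1 = frag[:rl]
        m2 = revcomp(frag[-rl:])
        # truth coordinates on the forward strand of the reference
        if not flip[i]:
            t1 = ReadTruth(chrom_ids[ci], start, "+")
            t2 = ReadTruth(chrom_ids[ci], start + flen - rl, "-")
        else:
            t1 = ReadTruth(chrom_ids[ci], start + flen - rl, "-")
            t2 = ReadTruth(chrom_ids[ci], start, "+")
        for mate, (seq, t) in enumerate(((m1, t1), (m2, t2)), start=1):
            if params.error_rate > 0:
                arr = np.frombuffer(seq.encode(), dtype="S1")
                seq = _mutate(rng, arr, params.error_rate).tobytes().decode()
            rid = f"sim{i}/{mate}"
            reads.append(
                Read(id=rid, sequence=seq, pair_id=f"sim{i}", mate_index=mate)
            )
            truth[rid] = t
    return reads, truth


def write_truth(truth: dict[str, ReadTruth], path) -> None:
    """Write the read truth map as TSV: read_id, chromosome, 0-based start, strand."""
    with open(path, "w") as fh:
        for rid, t in truth.items():
            fh.write(f"{rid}\t{t.chromosome}\t{t.start}\t{t.strand}\n")
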