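"""Read tiling and per-tile assembly.

The assembly problem is decomposed into *read tiles*: subsets of read pairs
assembled completely independently (no communication between tiles, so tiles
may run serially or in parallel in any order with identical results).  The
initial tiling is random and even; later iterations replace it with
alignment-derived tiles.

Per tile, the k-mer size is chosen by an auto-k scheme: candidate odd k
values are sampled from a user range, each candidate assembly is scored by a
composite of read usage, total contig length and N50, and the best k per
tile is remembered and re-tried in subsequent rounds.  The composite rewards
coverage first and contiguity second, which avoids preferring a high-N50 but
low-coverage contig set.
"""

from __future__ import annotations

import math
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np

from . import dbg
from .metrics import n50
from .seq_io import Contig, ContigSet, Read, pair_up, read_fasta, write_fasta, write_fastq_interleaved


class ConfigurationError(ValueError):
    pass


@dataclass
class ReadTile:
    """A subset of read pairs assigned to one sub-assembly.

    Members are pair ids; both mates of a member always travel together, and
    a pair id appears at most once per tile.
    """

    index: int
    members: list[str]

    def __post_init__(self) -> None:
        if len(self.members) != len(set(self.members)):
            raise ValueError(f"tile {self.index}: duplicate pair ids")

    def reads(self, pairs: Mapping[str, tuple[Read, Read]]) -> list[Read]:
        out: list[Read] = []
        for pid in self.members:
            m1, m2 = pairs[pid]
            out.append(m1)
            out.append(m2)
        return out


@dataclass(frozen=True)
class AssemblyScore:
    """Quality summary of one tile assembly: reads incorporated, total contig
    length (over contigs passing the minimum length) and N50."""

    used_reads: int
    total_contig_length: int
    n50: int

    def __post_init__(self) -> None:
        if min(self.used_reads, self.total_contig_length, self.n50) < 0:
            raise ValueError("assembly score fields must be >= 0")


@dataclass
class KmerHistory:
    """Per-tile record of tried k-mer sizes, their scores, and the best k so far."""

    scores: dict[int, tuple[AssemblyScore, float]] = field(default_factory=dict)

    def record(self, k: int, score: AssemblyScore, composite: float) -> None:
        prev = self.scores.get(k)
        if prev is None or composite > prev[1]:
            self.scores[k] = (score, composite)

    @property
    def best_k(self) -> int | None:
        """The recorded k with the highest composite; ties break to smaller k."""
        if not self.scores:
            return None
        return min(self.scores, key=lambda k: (-self.scores[k][1], k))


# The assembler contract: (reads, k, params) -> (contigs, used_read_count).
# Must be pure with respect to inputs and any seed in params, so identical
# inputs reproduce identical outputs.
AssemblerContract = Callable[[Sequence[Read], int, Mapping], tuple[ContigSet, int]]


def builtin_assembler(
    reads: Sequence[Read], k: int, params: Mapping | None = None
) -> tuple[ContigSet, int]:
    """The built-in de Bruijn assembler wrapped in the assembler contract."""
    p = dict(params or {})
    return dbg.assemble(
        reads,
        k,
        min_contig=p.get("min_contig", 200),
        coverage_cutoff=p.get("coverage_cutoff", 2),
        label=p.get("label", "dbg"),
    )


class ExternalAssembler:
    """Adapter running an external assembler command as the contract.

    The command template receives ``{reads}`` (interleaved FASTQ), ``{k}``
    and ``{out}`` (expected contig FASTA path).  Untested by default; it
    exists so real off-the-shelf assemblers can be plugged in.
    """

    def __init__(self, command_template: str):
        self.command_template = command_template

    def __call__(
        self, reads: Sequence[Read], k: int, params: Mapping | None = None
    ) -> tuple[ContigSet, int]:
        with tempfile.TemporaryDirectory() as tmp:
            reads_path = Path(tmp) / "reads.fastq"
            out_path = Path(tmp) / "contigs.fasta"
            write_fastq_interleaved(reads, reads_path)
            cmd = self.command_template.format(reads=reads_path, k=k, out=out_path)
            subprocess.run(cmd, shell=True, check=True)
            contigs = read_fasta(out_path)
        return contigs, len(reads)


def partition_reads_random(
    reads: Sequence[Read], n_tiles: int, seed: int
) -> list[ReadTile]:
    """Randomly partition read pairs evenly into ``n_tiles`` disjoint tiles.

    Tile sizes (in pairs) differ by at most one; mates stay together;
    deterministic for a fixed seed.
    """
    if n_tiles < 1:
        raise ConfigurationError("tile count must be >= 1")
    pairs = pair_up(reads)
    pair_ids = list(pairs)
    if n_tiles > len(pair_ids):
        raise ConfigurationError(
            f"tile count {n_tiles} exceeds the number of read pairs {len(pair_ids)}"
        )
    rng = np.random.default_rng(seed)
    order = [pair_ids[i] for i in rng.permutation(len(pair_ids))]
    base, extra = divmod(len(order), n_tiles)
    tiles: list[ReadTile] = []
    pos = 0
    for t in range(n_tiles):
        size = base + (1 if t < extra else 0)
        tiles.append(ReadTile(index=t, members=order[pos : pos + size]))
        pos += size
    return tiles


def assemble_tile(
    tile_reads: Sequence[Read],
    k: int,
    min_contig: int = 200,
    coverage_cutoff: int = 2,
    label: str = "tile",
    assembler: AssemblerContract = builtin_assembler,
) -> tuple[ContigSet, int]:
    """Assemble one tile's reads at k-mer size ``k`` via the assembler contract."""
    if not tile_reads:
        return ContigSet(label=label), 0
    max_len = max(len(r.sequence) for r in tile_reads)
    if k >= max_len:
        return ContigSet(label=label), 0
    return assembler(
        tile_reads,
        k,
        {"min_contig": min_contig, "coverage_cutoff": coverage_cutoff, "label": label},
    )


def score_assembly(
    contigs: ContigSet, used_reads: int, tile_read_total: int
) -> tuple[AssemblyScore, float]:
    """Score one candidate assembly.

    composite = (used_reads / tile_read_total) * total_contig_length * sqrt(N50).
    The usage factor penalizes high-N50/low-coverage contig sets; the
    composite is 0 exactly when there are no contigs.
    """
    if tile_read_total < used_reads:
        raise ValueError("tile_read_total must be >= used_reads")
    lengths = contigs.lengths()
    total = sum(lengths)
    n50_val = n50(lengths)
    score = AssemblyScore(
        used_reads=used_reads, total_contig_length=total, n50=n50_val
    )
    if total == 0 or tile_read_total == 0:
        return score, 0.0
    composite = (used_reads / tile_read_total) * total * math.sqrt(n50_val)
    return score, composite


def select_kmers(
    history: KmerHistory,
    k_range: tuple[int, int],
    n_candidates: int = 3,
    seed: int = 0,
) -> list[int]:
    """Pick the k-mer sizes to try in one assembly round.

    The per-tile best k so far is always retained; the remaining slots are
    filled with distinct odd values sampled uniformly from ``k_range``,
    excluding values already tried (their scores are on record, so re-trying
    a dominated k is wasted work).  When the range is exhausted, whatever is
    available is returned.  Deterministic per seed.
    """
    k_min, k_max = k_range
    if k_min % 2 == 0 or k_max % 2 == 0:
        raise ConfigurationError("k range bounds must be odd")
    if k_min > k_max:
        raise ConfigurationError("k_min must be <= k_max")
    if n_candidates < 1:
        raise ConfigurationError("n_candidates must be >= 1")
    odds = list(range(k_min, k_max + 1, 2))
    chosen: list[int] = []
    best = history.best_k
    if best is not None:
        chosen.append(best)
    pool = [k for k in odds if k not in history.scores and k not in chosen]
    rng = np.random.default_rng(seed)
    rng.shuffle(pool)
    for k in pool:
        if len(chosen) >= n_candidates:
            break
        chosen.append(k)
    if len(chosen) < n_candidates:
        # range exhausted: fall back to re-trying recorded values
        for k in sorted(history.scores):
            if len(chosen) >= n_candidates:
                break
            if k not in chosen:
                chosen.append(k)
    return chosen


def merge_contig_sets(
    sets: Sequence[ContigSet], label: str = "merged", iteration: int | None = None
) -> ContigSet:
    """Union of per-tile contig sets — the intermediate reference genome.

    Contigs are re-identified as ``t<tile>_<original id>`` so ids stay unique
    across tiles.
    """
    contigs: list[Contig] = []
    for t, cs in enumerate(sets):
        for c in cs:
            contigs.append(
                Contig(
                    id=f"t{t}_{c.id}",
                    sequence=c.sequence,
                    source_tile=t,
                    source_iteration=iteration,
                )
            )
    return ContigSet(contigs=contigs, label=label)


def default_elongation_k(merged: ContigSet, k_cap: int = 96) -> int:
    """Largest odd k <= min(k_cap, shortest contig length - 1)."""
    shortest = min(c.length for c in merged)
    k = min(k_cap, shortest - 1)
    if k % 2 == 0:
        k -= 1
    return k


@dataclass
class ElongationResult:
    contigs: ContigSet
    improved: bool
    merged_score: float
    elongated_score: float


def _distinct_content_score(contigs: ContigSet, k: int) -> tuple[float, int]:
    """Duplication-insensitive composite: distinct canonical k-mer count in
    place of raw total length, times sqrt(N50).  Raw length would reward a
    merged set for carrying the same sequence twice."""
    if len(contigs) == 0:
        return 0.0, 0
    distinct = dbg.distinct_kmer_count([c.sequence for c in contigs], k)
    return distinct * math.sqrt(n50(contigs.lengths())), len(contigs)


def elongate_merged_detailed(
    merged: ContigSet,
    k_long: int | None = None,
    min_contig: int = 200,
    label: str = "elongated",
) -> ElongationResult:
    """Re-assemble the merged contig set treating contigs as long error-free
    reads (coverage cutoff 1, no tip clipping), joining contigs that overlap
    by at least ``k_long`` bases and collapsing exact duplicates.

    The elongated set replaces the merged set when its duplication-insensitive
    composite score is strictly higher, or equal with fewer contigs (pure
    deduplication); otherwise the merged set is returned unchanged.
    """
    if len(merged) == 0:
        raise ValueError("merged contig set is empty")
    if k_long is None:
        k_long = default_elongation_k(merged)
    if k_long < 3 or all(c.length < k_long for c in merged):
        return ElongationResult(merged, False, 0.0, 0.0)
    elongated, _ = dbg.assemble(
        [c.sequence for c in merged],
        k_long,
        min_contig=min_contig,
        coverage_cutoff=1,
        clip=False,
        bubbles=True,
        label=label,
    )
    m_score, m_count = _distinct_content_score(merged, k_long)
    e_score, e_count = _distinct_content_score(elongated, k_long)
    improved = e_score > m_score or (e_score == m_score and e_count < m_count)
    return ElongationResult(
        contigs=elongated if improved else merged,
        improved=improved,
        merged_score=m_score,
        elongated_score=e_score,
    )


def elongate_merged(
    merged: ContigSet, k_long: int | None = None, min_contig: int = 200
) -> ContigSet:
    """Contract-shaped front of :func:`elongate_merged_detailed`."""
    return elongate_merged_detailed(merged, k_long=k_long, min_contig=min_contig).contigs
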