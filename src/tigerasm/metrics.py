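"""Assembly-quality metrics: N50, NG50, error-corrected NG50, genome
coverage and duplication, backed by an exact-anchor contig-to-reference
evaluator.

The evaluator is designed for synthetic, substitution-dominated data: it
finds exact anchors (unique ``anchor_length``-mers of the reference), chains
collinear anchors into blocks, and classifies the junctions between blocks
as SNP runs, indels, or misjoins.  The error-corrected NG50 is the NG50
after splitting every contig at each misjoin and at each indel strictly
longer than ``indel_split_threshold`` bp.  Evaluation of real genomes with
structural complexity is out of scope and delegated to dedicated alignment
tooling.

A minimum contig length (default 200 bp) is applied before all metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from ._dna import canonical, revcomp
from .seq_io import ContigSet


def n50(lengths: Iterable[int]) -> int:
    """Smallest length L such that contigs of length >= L sum to at least
    half the total assembly length; 0 for an empty input."""
    ls = sorted(lengths, reverse=True)
    total = sum(ls)
    if total == 0:
        return 0
    half = total / 2
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    return 0  # unreachable


def ng50(lengths: Iterable[int], genome_size: int) -> int:
    """Smallest contig length L such that contigs of length >= L sum to at
    least half the *reference genome*; 0 when even the full assembly falls
    short of half the genome."""
    if genome_size < 1:
        raise ValueError("genome_size must be >= 1")
    ls = sorted(lengths, reverse=True)
    half = genome_size / 2
    acc = 0
    for L in ls:
        acc += L
        if acc >= half:
            return L
    return 0


@dataclass(frozen=True)
class Block:
    """One collinear exact-match run between a contig and the reference.

    Intervals are 0-based half-open; ``contig_interval`` is on the contig,
    ``ref_interval`` on the forward reference strand.
    """

    chromosome: str
    strand: str
    contig_interval: tuple[int, int]
    ref_interval: tuple[int, int]


@dataclass(frozen=True)
class Breakpoint:
    position: int  # on the contig, in (0, contig length)
    kind: str  # "misjoin" or "indel"
    indel_length: int = 0


@dataclass
class ContigAlignment:
    """Alignment summary of one contig: its primary placement, the full block
    list, junction breakpoints (strictly increasing contig positions) and the
    SNP count inside matched blocks."""

    contig_id: str
    contig_length: int
    aligned: bool
    chromosome: str | None = None
    strand: str | None = None
    ref_interval: tuple[int, int] | None = None
    blocks: list[Block] = field(default_factory=list)
    breakpoints: list[Breakpoint] = field(default_factory=list)
    snps: int = 0

    def fragment_lengths(self, indel_split_threshold: int = 5) -> list[int]:
        """Lengths after splitting at every misjoin and at every indel longer
        than the threshold (strictly).  Fragments always sum to the contig
        length."""
        cuts = [
            bp.position
            for bp in self.breakpoints
            if bp.kind == "misjoin"
            or (bp.kind == "indel" and bp.indel_length > indel_split_threshold)
        ]
        frags: list[int] = []
        prev = 0
        for c in cuts:
            frags.append(c - prev)
            prev = c
        frags.append(self.contig_length - prev)
        return frags


def _build_anchor_index(
    reference: ContigSet, anchor_length: int
) -> dict[str, tuple[str, int, str]]:
    """Map canonical anchor -> (chromosome, forward position, orientation of
    the stored forward anchor), for anchors occurring exactly once in the
    reference counting both strands."""
    occurrences: dict[str, list[tuple[str, int, str]]] = {}
    for chrom in reference:
        seq = chrom.sequence
        for i in range(len(seq) - anchor_length + 1):
            a = seq[i : i + anchor_length]
            if "N" in a:
                continue
            c = canonical(a)
            lst = occurrences.setdefault(c, [])
            if len(lst) < 2:
                lst.append((chrom.id, i, "+" if a == c else "-"))
            else:
                lst.append((chrom.id, i, "x"))  # marker beyond uniqueness
    return {c: lst[0] for c, lst in occurrences.items() if len(lst) == 1}


def _scan_anchors(contig_seq: str, index, anchor_length: int):
    """Yield (contig position, chromosome, ref position, strand) anchor matches."""
    for i in range(len(contig_seq) - anchor_length + 1):
        a = contig_seq[i : i + anchor_length]
        if "N" in a:
            continue
        c = canonical(a)
        hit = index.get(c)
        if hit is None:
            continue
        chrom, rpos, ref_orient = hit
        query_orient = "+" if a == c else "-"
        strand = "+" if query_orient == ref_orient else "-"
        yield i, chrom, rpos, strand


def _chain_blocks(matches, anchor_length: int) -> list[Block]:
    """Chain anchor matches sharing chromosome, strand and diagonal into blocks.

    On the forward strand the diagonal is ref_pos - contig_pos; on the
    reverse it is ref_pos + contig_pos.  Anchor gaps on the same diagonal do
    not break a block (the intervening sequence is compared for SNPs later).
    """
    blocks: list[Block] = []
    cur = None  # (chrom, strand, diag, c_first, c_last, r_min, r_max)
    for i, chrom, rpos, strand in matches:
        diag = rpos - i if strand == "+" else rpos + i
        if cur is not None and cur[0] == chrom and cur[1] == strand and cur[2] == diag:
            cur = (chrom, strand, diag, cur[3], i, min(cur[5], rpos), max(cur[6], rpos))
            continue
        if cur is not None:
            blocks.append(_close_block(cur, anchor_length))
        cur = (chrom, strand, diag, i, i, rpos, rpos)
    if cur is not None:
        blocks.append(_close_block(cur, anchor_length))
    return blocks


def _close_block(cur, anchor_length: int) -> Block:
    chrom, strand, _diag, c_first, c_last, r_min, r_max = cur
    return Block(
        chromosome=chrom,
        strand=strand,
        contig_interval=(c_first, c_last + anchor_length),
        ref_interval=(r_min, r_max + anchor_length),
    )


_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _extend_terminal(
    block: Block, contig_seq: str, ref_seq: str, anchor_length: int,
    left: bool, right: bool,
) -> Block:
    """Extend a contig-terminal block along its diagonal while the bases
    match exactly.  Unique anchors cannot reach into repeat interiors, so a
    contig ending inside a repeat copy would otherwise lose a perfectly
    matching tail."""
    cs, ce = block.contig_interval
    rs, re_ = block.ref_interval
    rlen = len(ref_seq)
    clen = len(contig_seq)
    if block.strand == "+":
        if left:
            while cs > 0 and rs > 0 and contig_seq[cs - 1] == ref_seq[rs - 1]:
                cs -= 1
                rs -= 1
        if right:
            while ce < clen and re_ < rlen and contig_seq[ce] == ref_seq[re_]:
                ce += 1
                re_ += 1
    else:
        if left:  # extending the contig start consumes reference to the right
            while cs > 0 and re_ < rlen and contig_seq[cs - 1] == _COMP[ref_seq[re_]]:
                cs -= 1
                re_ += 1
        if right:
            while ce < clen and rs > 0 and contig_seq[ce] == _COMP[ref_seq[rs - 1]]:
                ce += 1
                rs -= 1
    return Block(block.chromosome, block.strand, (cs, ce), (rs, re_))


def _count_block_snps(block: Block, contig_seq: str, ref_seq: str) -> int:
    """Mismatches between a block's contig span and its reference span (the
    spans have equal length by construction; anchors only guarantee exact
    match at anchor positions, substituted columns can sit between them)."""
    cs, ce = block.contig_interval
    rs, re_ = block.ref_interval
    sub_c = contig_seq[cs:ce]
    sub_r = ref_seq[rs:re_]
    if block.strand == "-":
        sub_r = revcomp(sub_r)
    return sum(1 for x, y in zip(sub_c, sub_r) if x != y)


def align_contigs_to_reference(
    contigs: ContigSet,
    reference: ContigSet,
    anchor_length: int = 50,
    max_gap: int = 1000,
) -> list[ContigAlignment]:
    """Align each contig to the reference by unique exact anchors.

    Junctions between adjacent blocks are classified: same chromosome and
    strand with a small diagonal shift and both gaps within ``max_gap`` is an
    indel of the shift length; anything else (chromosome/strand switch, or a
    jump beyond ``max_gap``) is a misjoin.  Contigs with no anchor are
    reported unaligned.
    """
    if len(reference) == 0:
        raise ValueError("reference is empty")
    index = _build_anchor_index(reference, anchor_length)
    ref_seqs = {c.id: c.sequence for c in reference}
    out: list[ContigAlignment] = []
    for contig in contigs:
        matches = list(_scan_anchors(contig.sequence, index, anchor_length))
        if not matches:
            out.append(
                ContigAlignment(
                    contig_id=contig.id, contig_length=contig.length, aligned=False
                )
            )
            continue
        blocks = _chain_blocks(matches, anchor_length)
        blocks[0] = _extend_terminal(
            blocks[0], contig.sequence, ref_seqs[blocks[0].chromosome],
            anchor_length, left=True, right=len(blocks) == 1,
        )
        if len(blocks) > 1:
            blocks[-1] = _extend_terminal(
                blocks[-1], contig.sequence, ref_seqs[blocks[-1].chromosome],
                anchor_length, left=False, right=True,
            )
        snps = sum(_count_block_snps(b, contig.sequence, ref_seqs[b.chromosome]) for b in blocks)
        breakpoints: list[Breakpoint] = []
        for prev, nxt in zip(blocks, blocks[1:]):
            pos = prev.contig_interval[1]
            pos = max(1, min(pos, contig.length - 1))
            contig_gap = nxt.contig_interval[0] - prev.contig_interval[1]
            if prev.chromosome == nxt.chromosome and prev.strand == nxt.strand:
                if prev.strand == "+":
                    ref_gap = nxt.ref_interval[0] - prev.ref_interval[1]
                else:
                    ref_gap = prev.ref_interval[0] - nxt.ref_interval[1]
                shift = abs(ref_gap - contig_gap)
                ordered = ref_gap >= -(contig_gap + max_gap)
                if (
                    ordered
                    and abs(ref_gap) <= max_gap
                    and abs(contig_gap) <= max_gap
                    and shift > 0
                ):
                    breakpoints.append(Breakpoint(pos, "indel", shift))
                    continue
                if shift == 0 and abs(ref_gap) <= max_gap:
                    # pure substitution run between blocks; not a breakpoint
                    continue
            breakpoints.append(Breakpoint(pos, "misjoin"))
        # keep breakpoint positions strictly increasing
        cleaned: list[Breakpoint] = []
        for bp in breakpoints:
            if cleaned and bp.position <= cleaned[-1].position:
                continue
            cleaned.append(bp)
        primary = max(
            blocks, key=lambda b: b.ref_interval[1] - b.ref_interval[0]
        )
        out.append(
            ContigAlignment(
                contig_id=contig.id,
                contig_length=contig.length,
                aligned=True,
                chromosome=primary.chromosome,
                strand=primary.strand,
                ref_interval=primary.ref_interval,
                blocks=blocks,
                breakpoints=cleaned,
                snps=snps,
            )
        )
    return out


def corrected_ng50(
    alignments: Sequence[ContigAlignment],
    genome_size: int,
    indel_split_threshold: int = 5,
) -> int:
    """NG50 of the contig fragments obtained by splitting each contig at
    every misjoin and at every indel longer than the threshold."""
    frags: list[int] = []
    for a in alignments:
        frags.extend(a.fragment_lengths(indel_split_threshold))
    return ng50(frags, genome_size)


def coverage_and_duplication(
    alignments: Sequence[ContigAlignment], reference: ContigSet
) -> tuple[float, float, float]:
    """(genome coverage %, unaligned reference %, duplication %).

    Coverage is the fraction of reference bases covered by at least one
    aligned block; duplication is the per-base excess depth
    (sum of max(0, depth - 1)) as a percentage of the genome size.
    """
    genome_size = reference.total_length
    depth = {c.id: np.zeros(c.length + 1, dtype=np.int64) for c in reference}
    for a in alignments:
        for b in a.blocks:
            d = depth[b.chromosome]
            d[b.ref_interval[0]] += 1
            d[b.ref_interval[1]] -= 1
    covered = 0
    excess = 0
    for c in reference:
        prof = np.cumsum(depth[c.id][:-1])
        covered += int(np.count_nonzero(prof))
        excess += int(np.maximum(prof - 1, 0).sum())
    coverage = 100.0 * covered / genome_size
    return coverage, 100.0 - coverage, 100.0 * excess / genome_size


@dataclass
class EvalReport:
    """Assembly-vs-reference report: continuity (N50/NG50), accuracy
    (corrected NG50, SNPs, indels, misjoins) and genome statistics."""

    contig_count: int
    n50: int
    ng50: int
    corrected_ng50: int
    genome_coverage: float
    unaligned_ref: float
    duplication: float
    snps: int = 0
    indels: int = 0
    misjoins: int = 0

    def to_tsv(self) -> str:
        keys = [
            "contig_count", "n50", "ng50", "corrected_ng50",
            "genome_coverage", "unaligned_ref", "duplication",
            "snps", "indels", "misjoins",
        ]
        vals = [getattr(self, k) for k in keys]
        return (
            "\t".join(keys)
            + "\n"
            + "\t".join(f"{v:.2f}" if isinstance(v, float) else str(v) for v in vals)
            + "\n"
        )

    def pretty(self) -> str:
        return (
            f"contigs {self.contig_count}  N50 {self.n50}  NG50 {self.ng50}  "
            f"NG50corr {self.corrected_ng50}  coverage {self.genome_coverage:.2f}%  "
            f"duplication {self.duplication:.2f}%  "
            f"SNP {self.snps}  indel {self.indels}  misjoin {self.misjoins}"
        )


def evaluate(
    contigs: ContigSet,
    reference: ContigSet,
    min_contig: int = 200,
    anchor_length: int = 50,
    max_gap: int = 1000,
    indel_split_threshold: int = 5,
) -> EvalReport:
    """Full evaluation of an assembly against a reference genome.

    Contigs shorter than ``min_contig`` are dropped before any statistic is
    computed.
    """
    kept = ContigSet(
        contigs=[c for c in contigs if c.length >= min_contig], label=contigs.label
    )
    genome_size = reference.total_length
    lengths = kept.lengths()
    alignments = align_contigs_to_reference(
        kept, reference, anchor_length=anchor_length, max_gap=max_gap
    )
    cov, unal, dup = coverage_and_duplication(alignments, reference)
    return EvalReport(
        contig_count=len(kept),
        n50=n50(lengths),
        ng50=ng50(lengths, genome_size),
        corrected_ng50=corrected_ng50(alignments, genome_size, indel_split_threshold),
        genome_coverage=cov,
        unaligned_ref=unal,
        duplication=dup,
        snps=sum(a.snps for a in alignments),
        indels=sum(1 for a in alignments for b in a.breakpoints if b.kind == "indel"),
        misjoins=sum(
            1 for a in alignments for b in a.breakpoints if b.kind == "misjoin"
        ),
    )


def write_bed(alignments: Sequence[ContigAlignment], path) -> None:
    """Dump aligned blocks as BED: chrom, start, end, contig_id, 0, strand."""
    with open(path, "w") as fh:
        for a in alignments:
            for b in a.blocks:
                fh.write(
                    f"{b.chromosome}\t{b.ref_interval[0]}\t{b.ref_interval[1]}"
                    f"\t{a.contig_id}\t0\t{b.strand}\n"
                )
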