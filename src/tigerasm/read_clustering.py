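"""Read clustering: align every input read to each contig cluster and
collect well-clustered read tiles.

The aligner is an internal seed-and-verify matcher: each cluster's contigs
are indexed by every canonical seed-length substring (stride 1); a read is
looked up by its first, middle and last seeds and every candidate placement
is verified end-to-end with at most ``max_mismatch`` substitutions.  Gapped
alignment is out of scope — the data model upstream is substitution-only.
An external aligner can satisfy the same contract through FASTA/TSV
adapters.

Collection rules: a pair joins the tile of cluster c when at least one mate
aligns to any contig of c; both mates always enter together (mate rescue);
a pair is collected at most once per cluster but may appear in several
clusters when similar contigs ended up apart.  Pairs aligning nowhere go to
an ``unplaced`` pool for the caller to recycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from ._dna import canonical, count_mismatches, revcomp
from .contig_clustering import ContigClusterSet
from .seq_io import ContigSet, Read, pair_up
from .tile_assembly import ReadTile


@dataclass(frozen=True)
class AlignmentHit:
    read_id: str
    contig_id: str
    position: int  # 0-based start of the (forward-oriented) read on the contig
    strand: str  # '+' or '-'
    mismatches: int


@dataclass
class ReadAligner:
    """Seed index over one cluster's contigs: canonical seed -> placements."""

    seed_length: int
    contigs: dict[str, str]
    index: dict[str, list[tuple[str, int, str]]] = field(default_factory=dict)


def build_read_aligner(cluster_contigs: ContigSet, seed_length: int = 20) -> ReadAligner:
    """Index every seed-length substring (stride 1) of every contig.

    Each posting stores the contig, the position, and whether the forward
    contig substring equals the canonical seed ('+') or its reverse
    complement ('-').  Empty contig sets produce an index that aligns
    nothing.
    """
    aligner = ReadAligner(
        seed_length=seed_length, contigs={c.id: c.sequence for c in cluster_contigs}
    )
    for c in cluster_contigs:
        seq = c.sequence
        for i in range(len(seq) - seed_length + 1):
            s = seq[i : i + seed_length]
            if "N" in s:
                continue
            cs = canonical(s)
            aligner.index.setdefault(cs, []).append(
                (c.id, i, "+" if s == cs else "-")
            )
    return aligner


def align_read(read: Read, aligner: ReadAligner, max_mismatch: int = 2) -> list[AlignmentHit]:
    """Seed-and-verify alignment of one read against the indexed contigs.

    Seeds are taken at the read's start, middle and end; every candidate
    placement implied by a seed hit is verified full-length (the read must
    lie entirely within the contig) and reported when it has at most
    ``max_mismatch`` substitutions.  All distinct verified placements are
    returned, sorted deterministically.
    """
    L = aligner.seed_length
    seq = read.sequence
    rl = len(seq)
    if rl < L:
        return []
    offsets = sorted({0, (rl - L) // 2, rl - L})
    candidates: set[tuple[str, int, str]] = set()
    for o in offsets:
        s = seq[o : o + L]
        if "N" in s:
            continue
        cs = canonical(s)
        postings = aligner.index.get(cs)
        if not postings:
            continue
        q_orient = "+" if s == cs else "-"
        for cid, pos, r_orient in postings:
            if q_orient == r_orient:
                candidates.add((cid, pos - o, "+"))
            else:
                candidates.add((cid, pos - (rl - o - L), "-"))
    hits: list[AlignmentHit] = []
    rc_seq: str | None = None
    for cid, start, strand in sorted(candidates):
        if start < 0:
            continue
        contig = aligner.contigs[cid]
        if start + rl > len(contig):
            continue
        if strand == "+":
            query = seq
        else:
            if rc_seq is None:
                rc_seq = revcomp(seq)
            query = rc_seq
        mm = count_mismatches(query, contig[start : start + rl], limit=max_mismatch)
        if mm <= max_mismatch:
            hits.append(
                AlignmentHit(
                    read_id=read.id,
                    contig_id=cid,
                    position=start,
                    strand=strand,
                    mismatches=mm,
                )
            )
    return hits


@dataclass
class ClusterReadTiles:
    """Per-cluster read tiles plus the pair -> clusters membership map and
    the pool of pairs that aligned to no cluster."""

    tiles: list[ReadTile]
    membership: dict[str, set[int]]
    unplaced: list[str]


def cluster_reads(
    all_reads: Sequence[Read],
    clusters: ContigClusterSet,
    contigs: ContigSet,
    seed_length: int = 20,
    max_mismatch: int = 2,
    multiplicity_cap: bool = True,
) -> ClusterReadTiles:
    """Collect one read tile per contig cluster.

    A pair enters tile c iff either mate has at least one verified hit on a
    contig of cluster c (both mates are then collected: mate rescue).  With
    ``multiplicity_cap`` enabled, a pair hitting more than half of all
    clusters is kept only in its best cluster (fewest mismatches, then
    lowest cluster index) — a guard against high-copy repeats duplicating
    work everywhere; disable it for oracle-style exhaustive collection.
    """
    if clusters.n_clusters == 0:
        raise ValueError("no clusters given")
    by_id = contigs.by_id()
    aligners = []
    for members in clusters.clusters:
        sub = ContigSet(contigs=[by_id[cid] for cid in members if cid in by_id])
        aligners.append(build_read_aligner(sub, seed_length))

    pairs = pair_up(all_reads)
    C = clusters.n_clusters
    membership: dict[str, set[int]] = {}
    unplaced: list[str] = []
    tile_members: list[list[str]] = [[] for _ in range(C)]

    for pid in pairs:
        m1, m2 = pairs[pid]
        per_mate: list[dict[int, int]] = []  # per mate: cluster -> best mismatches
        for mate in (m1, m2):
            hits: dict[int, int] = {}
            for ci in range(C):
                best: int | None = None
                for h in align_read(mate, aligners[ci], max_mismatch):
                    if best is None or h.mismatches < best:
                        best = h.mismatches
                if best is not None:
                    hits[ci] = best
            per_mate.append(hits)
        hit_clusters: dict[int, int] = {}
        for hits in per_mate:
            for ci, mm in hits.items():
                if ci not in hit_clusters or mm < hit_clusters[ci]:
                    hit_clusters[ci] = mm
        if not hit_clusters:
            unplaced.append(pid)
            continue
        chosen = set(hit_clusters)
        if multiplicity_cap and len(chosen) > C / 2:
            # A promiscuous (repeat-borne) pair is anchored by its most
            # *specific* evidence: the mate hitting the fewest clusters
            # decides, preferring clusters both mates support, then fewest
            # mismatches, then the lowest index for determinism.
            specific = min(
                (h for h in per_mate if h), key=len, default=hit_clusters
            )
            both = set(per_mate[0]) & set(per_mate[1])
            pool = (set(specific) & both) or set(specific)
            best_ci = min(pool, key=lambda ci: (hit_clusters[ci], ci))
            chosen = {best_ci}
        membership[pid] = chosen
        for ci in sorted(chosen):
            tile_members[ci].append(pid)

    tiles = [ReadTile(index=ci, members=tile_members[ci]) for ci in range(C)]
    return ClusterReadTiles(tiles=tiles, membership=membership, unplaced=unplaced)


def write_hits_tsv(hits: Sequence[AlignmentHit], path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                f"{h.read_id}\t{h.contig_id}\t{h.position}\t{h.strand}\t{h.mismatches}\n"
            )


def brute_force_align(
    read: Read, contigs: ContigSet | Mapping[str, str], max_mismatch: int = 2
) -> list[AlignmentHit]:
    """Exhaustive placement scan on both strands — the independent oracle the
    seed-and-verify aligner is tested against on small fixtures."""
    seqs = contigs if isinstance(contigs, Mapping) else {c.id: c.sequence for c in contigs}
    seq = read.sequence
    rc_seq = revcomp(seq)
    rl = len(seq)
    hits: list[AlignmentHit] = []
    for cid in sorted(seqs):
        contig = seqs[cid]
        for start in range(len(contig) - rl + 1):
            window = contig[start : start + rl]
            for strand, query in (("+", seq), ("-", rc_seq)):
                mm = count_mismatches(query, window, limit=max_mismatch)
                if mm <= max_mismatch:
                    hits.append(AlignmentHit(read.id, cid, start, strand, mm))
    return hits
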