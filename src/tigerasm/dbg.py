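"""Built-in reference de Bruijn graph (DBG) assembler.

This is the embedded assembler the tiled pipeline uses by default.  It
implements the conventional short-read DBG recipe:

* nodes are canonical k-mers (a k-mer and its reverse complement are one
  node; k must be odd so no k-mer is its own reverse complement);
* k-mers below a coverage cutoff are dropped;
* tips (dead-end paths) shorter than 2k bp are clipped;
* simple bubbles (two paths sharing entry and exit nodes) are popped,
  keeping the higher-coverage path;
* contigs are maximal non-branching paths at least ``min_contig`` bp long.

The graph lives in plain dicts keyed by canonical k-mer strings.  Oriented
adjacency (which of the up to four (k-1)-overlap extensions exist, per
orientation) is computed once per assembly and filtered against the live
k-mer table afterwards, so tip clipping and bubble popping never pay for
re-deriving neighbours.  Everything is deterministic: identical reads and
parameters give identical contigs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from ._dna import revcomp
from .seq_io import Contig, ContigSet, Read

_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# An oriented node is (canonical_kmer, orientation) with orientation '+'
# meaning the canonical spelling itself and '-' its reverse complement.
OrientedNode = tuple[str, str]


def count_kmers(sequences: Iterable[str], k: int) -> dict[str, int]:
    """Count canonical k-mers over all sequences; windows containing N are skipped."""
    counts: dict[str, int] = {}
    for seq in sequences:
        n = len(seq)
        for i in range(n - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            rc = revcomp(kmer)
            if rc < kmer:
                kmer = rc
            counts[kmer] = counts.get(kmer, 0) + 1
    return counts


class _Graph:
    """Canonical-k-mer graph with precomputed oriented adjacency.

    ``adj[km]`` holds two tuples of (neighbour canonical k-mer, neighbour
    orientation): successors of the '+' orientation and of the '-'
    orientation.  Predecessors of (km, o) are the flipped successors of the
    opposite orientation.  Neighbour lists are filtered against the live
    ``table`` at query time, so removing k-mers needs no adjacency rebuild.
    """

    def __init__(self, table: dict[str, int], k: int):
        self.table = table
        self.k = k
        self.adj: dict[str, tuple[tuple[OrientedNode, ...], tuple[OrientedNode, ...]]] = {}
        for km in table:
            self.adj[km] = (self._raw_succ(km), self._raw_succ(revcomp(km)))

    def _raw_succ(self, oriented_seq: str) -> tuple[OrientedNode, ...]:
        suffix = oriented_seq[1:]
        out = []
        for b in _BASES:
            t = suffix + b
            rc = revcomp(t)
            c = t if t <= rc else rc
            if c in self.table:
                out.append((c, "+" if t == c else "-"))
        return tuple(out)

    def successors(self, node: OrientedNode) -> list[OrientedNode]:
        km, o = node
        raw = self.adj[km][0 if o == "+" else 1]
        return [n for n in raw if n[0] in self.table]

    def predecessors(self, node: OrientedNode) -> list[OrientedNode]:
        km, o = node
        raw = self.adj[km][1 if o == "+" else 0]
        return [
            (c, "-" if no == "+" else "+") for c, no in raw if c in self.table
        ]

    def remove(self, kmers: Iterable[str]) -> None:
        for km in kmers:
            self.table.pop(km, None)


@dataclass
class Unitig:
    """A maximal non-branching path, spelled in one arbitrary orientation."""

    sequence: str
    kmers: list[str]  # canonical forms, in path order
    first: OrientedNode
    last: OrientedNode

    @property
    def length(self) -> int:
        return len(self.sequence)

    def mean_coverage(self, table: dict[str, int]) -> float:
        return sum(table[k] for k in self.kmers) / len(self.kmers)


def _spell(path: list[OrientedNode], k: int) -> str:
    km, o = path[0]
    chars = [km if o == "+" else revcomp(km)]
    for c, no in path[1:]:
        chars.append(c[-1] if no == "+" else _COMP[c[0]])
    return "".join(chars)


def _walk(graph: _Graph, start: OrientedNode, visited: set[str]) -> list[OrientedNode]:
    """Extend forward from ``start`` while the path stays non-branching."""
    path = [start]
    cur = start
    while True:
        succ = graph.successors(cur)
        if len(succ) != 1:
            break
        nxt = succ[0]
        if nxt[0] in visited:
            break
        if len(graph.predecessors(nxt)) != 1:
            break
        visited.add(nxt[0])
        path.append(nxt)
        cur = nxt
    return path


def _flip(node: OrientedNode) -> OrientedNode:
    return (node[0], "-" if node[1] == "+" else "+")


def build_unitigs(graph: _Graph) -> list[Unitig]:
    """Extract all maximal non-branching paths.

    Each unitig is reported once (not also as its reverse complement);
    iterating canonical k-mers in sorted order makes the output
    deterministic.
    """
    visited: set[str] = set()
    unitigs: list[Unitig] = []
    for start in sorted(graph.table):
        if start in visited:
            continue
        visited.add(start)
        fwd = _walk(graph, (start, "+"), visited)
        bwd = _walk(graph, (start, "-"), visited)
        path = [_flip(n) for n in reversed(bwd[1:])] + fwd
        unitigs.append(
            Unitig(
                sequence=_spell(path, graph.k),
                kmers=[c for c, _ in path],
                first=path[0],
                last=path[-1],
            )
        )
    return unitigs


def _external_ends(graph: _Graph, u: Unitig) -> tuple[list[OrientedNode], list[OrientedNode]]:
    """(predecessors of the unitig start, successors of the unitig end),
    excluding edges internal to the unitig itself."""
    own = set(u.kmers)
    preds = [n for n in graph.predecessors(u.first) if n[0] not in own]
    succs = [n for n in graph.successors(u.last) if n[0] not in own]
    return preds, succs


def clip_tips(graph: _Graph, max_rounds: int = 5) -> None:
    """Iteratively remove tips: paths shorter than 2k bp with exactly one
    dead end, attached to the rest of the graph at the other end."""
    limit = 2 * graph.k
    for _ in range(max_rounds):
        removed = False
        for u in build_unitigs(graph):
            if u.length >= limit:
                continue
            preds, succs = _external_ends(graph, u)
            if (len(preds) == 0) != (len(succs) == 0):
                graph.remove(u.kmers)
                removed = True
        if not removed:
            break


def pop_bubbles(
    graph: _Graph, max_length_delta: int = 5, max_coverage_ratio: float = 0.5
) -> None:
    """Pop simple bubbles: pairs of unitigs joining the same entry and exit
    nodes with near-equal length.  The lower-coverage path is removed (ties
    break toward keeping the lexicographically smaller k-mer path), but only
    when its mean coverage is below ``max_coverage_ratio`` times the
    keeper's: a deeply unbalanced bubble is a sequencing-error artefact,
    while balanced parallel paths are genuine near-identical sequence
    (diverged repeat copies, haplotypes) that popping would delete."""
    groups: dict[object, list[Unitig]] = {}
    for u in build_unitigs(graph):
        preds, succs = _external_ends(graph, u)
        if len(preds) != 1 or len(succs) != 1:
            continue
        a = (preds[0], succs[0])
        b = (_flip(succs[0]), _flip(preds[0]))  # same bubble traversed in reverse
        key = min(a, b)
        groups.setdefault(key, []).append(u)
    for key in sorted(groups):
        members = groups[key]
        if len(members) < 2:
            continue
        members.sort(key=lambda u: (-u.mean_coverage(graph.table), u.kmers[0]))
        keeper = members[0]
        keeper_cov = keeper.mean_coverage(graph.table)
        for u in members[1:]:
            if (
                abs(u.length - keeper.length) <= max_length_delta
                and u.mean_coverage(graph.table) < max_coverage_ratio * keeper_cov
            ):
                graph.remove(u.kmers)


def assemble(
    reads: Sequence[Read] | Sequence[str],
    k: int,
    min_contig: int = 200,
    coverage_cutoff: int = 2,
    clip: bool = True,
    bubbles: bool = True,
    label: str = "dbg",
) -> tuple[ContigSet, int]:
    """Assemble reads (or plain sequences) at k-mer size ``k``.

    Returns ``(contigs, used_reads)`` where ``used_reads`` counts the input
    reads contributing at least one k-mer that survived graph cleaning.
    Reads shorter than k contribute nothing; an empty surviving graph yields
    an empty contig set (not an error).
    """
    if k % 2 == 0:
        raise ValueError("k must be odd (avoids self-reverse-complement k-mers)")
    if k < 3:
        raise ValueError("k must be >= 3")
    seqs = [r.sequence if isinstance(r, Read) else r for r in reads]
    table = count_kmers(seqs, k)
    if coverage_cutoff > 1:
        table = {km: c for km, c in table.items() if c >= coverage_cutoff}
    graph = _Graph(table, k)
    if clip:
        clip_tips(graph)
    if bubbles:
        pop_bubbles(graph)

    unitigs = [u for u in build_unitigs(graph) if u.length >= min_contig]
    # Deterministic output order: longest first, sequence as tie-break.
    unitigs.sort(key=lambda u: (-u.length, u.sequence))
    contigs = [
        Contig(id=f"{label}_c{i}", sequence=u.sequence)
        for i, u in enumerate(unitigs)
    ]

    used = 0
    for seq in seqs:
        n = len(seq)
        for i in range(n - k + 1):
            km = seq[i : i + k]
            if "N" in km:
                continue
            rc = revcomp(km)
            if rc < km:
                km = rc
            if km in table:
                used += 1
                break
    return ContigSet(contigs=contigs, label=label), used


def distinct_kmer_count(reads: Sequence[Read] | Sequence[str], k: int) -> int:
    """Number of distinct canonical k-mers in a read collection (memory
    surrogate: the dominant cost of a DBG assembly scales with this count)."""
    seqs = [r.sequence if isinstance(r, Read) else r for r in reads]
    return len(count_kmers(seqs, k))
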