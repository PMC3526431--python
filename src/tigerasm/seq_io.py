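"""Sequence I/O: FASTA/FASTQ reading and writing plus the pairing conventions
used throughout the pipeline.

Paired-end FASTQ may arrive as two files (the n-th records of each file are
mates) or as one interleaved file (records alternate mate 1 / mate 2 of the
same fragment).  Pairing is positional, never name-based.  Quality strings are
carried through untouched but never interpreted: read error handling is
assumed to have happened upstream, so the core stays independent of quality
models.

All coordinates elsewhere in the package are 0-based, half-open.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from ._dna import VALID_CHARS


class FormatError(ValueError):
    """A sequence file violates the format contract (bad record, duplicate id...)."""


class PairingError(ValueError):
    """Mate files or interleaved records cannot be paired positionally."""


@dataclass(frozen=True)
class Read:
    """One sequencing read with mate linkage.

    ``pair_id`` is shared by both mates of a fragment; ``mate_index`` is 1 or
    2.  ``(pair_id, mate_index)`` is unique within a read set.
    """

    id: str
    sequence: str
    pair_id: str
    mate_index: int
    quality: str | None = None

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise FormatError(f"read {self.id!r} has an empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )
        if self.mate_index not in (1, 2):
            raise ValueError(f"mate_index must be 1 or 2, got {self.mate_index}")


@dataclass(frozen=True)
class Contig:
    """A contiguous assembled (or simulated) sequence.

    ``length`` always equals ``len(sequence)`` and is the vertex weight in the
    contig connectivity graph.  ``source_tile``/``source_iteration`` record
    provenance inside the iterative pipeline.
    """

    id: str
    sequence: str
    source_tile: int | None = None
    source_iteration: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class ContigSet:
    """An ordered collection of contigs with unique ids.

    The union of per-tile contig sets is the intermediate reference genome
    that drives read re-clustering between iterations.
    """

    contigs: list[Contig] = field(default_factory=list)
    label: str = ""

    def __post_init__(self) -> None:
        ids = [c.id for c in self.contigs]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            for i in ids:
                if i in seen:
                    raise FormatError(f"duplicate contig id {i!r} in set {self.label!r}")
                seen.add(i)

    def __len__(self) -> int:
        return len(self.contigs)

    def __iter__(self):
        return iter(self.contigs)

    def __getitem__(self, i: int) -> Contig:
        return self.contigs[i]

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.contigs)

    def lengths(self) -> list[int]:
        return [c.length for c in self.contigs]

    def by_id(self) -> dict[str, Contig]:
        return {c.id: c for c in self.contigs}


def _reads_from_records(records, which_mate: int | None, offset: int = 0) -> list[Read]:
    """Convert Biopython SeqRecords to Reads.

    ``which_mate`` fixes the mate index (two-file layout); ``None`` means
    interleaved (alternating 1/2).  Pair ids are positional: ``p<pair#>``.
    """
    reads: list[Read] = []
    for i, rec in enumerate(records):
        seq = str(rec.seq).upper()
        qual = None
        if "phred_quality" in rec.letter_annotations:
            qual = "".join(
                chr(q + 33) for q in rec.letter_annotations["phred_quality"]
            )
        if which_mate is None:
            pair_no, mate = divmod(i, 2)
            mate += 1
        else:
            pair_no, mate = i, which_mate
        try:
            reads.append(
                Read(
                    id=rec.id,
                    sequence=seq,
                    quality=qual,
                    pair_id=f"p{pair_no + offset}",
                    mate_index=mate,
                )
            )
        except FormatError as exc:
            raise FormatError(f"record {i}: {exc}") from exc
    return reads


def read_fastq(
    path_or_paths: str | os.PathLike | Sequence[str | os.PathLike],
    paired_layout: str = "two-file",
) -> list[Read]:
    """Read paired FASTQ into a list of :class:`Read`.

    ``paired_layout`` is ``"two-file"`` (two paths, positional mates) or
    ``"interleaved"`` (one path, alternating mates).  Record order is
    preserved: in two-file layout all mate-1 reads come first, then all
    mate-2 reads; interleaved order is kept as-is.
    """
    if paired_layout == "two-file":
        if isinstance(path_or_paths, (str, os.PathLike)):
            raise ValueError("two-file layout requires a pair of paths")
        p1, p2 = path_or_paths
        r1 = _reads_from_records(SeqIO.parse(str(p1), "fastq"), which_mate=1)
        r2 = _reads_from_records(SeqIO.parse(str(p2), "fastq"), which_mate=2)
        if len(r1) != len(r2):
            raise PairingError(
                f"mate files have {len(r1)} and {len(r2)} records; counts must match"
            )
        return r1 + r2
    if paired_layout == "interleaved":
        if not isinstance(path_or_paths, (str, os.PathLike)):
            (path_or_paths,) = path_or_paths
        reads = _reads_from_records(
            SeqIO.parse(str(path_or_paths), "fastq"), which_mate=None
        )
        if len(reads) % 2 != 0:
            raise PairingError(
                f"interleaved file has an odd record count ({len(reads)})"
            )
        return reads
    raise ValueError(f"unknown paired_layout {paired_layout!r}")


def write_fastq_interleaved(reads: Iterable[Read], path: str | os.PathLike) -> None:
    """Write reads as interleaved 4-line FASTQ (mates adjacent, pair order kept)."""
    by_pair: dict[str, dict[int, Read]] = {}
    order: list[str] = []
    for r in reads:
        if r.pair_id not in by_pair:
            by_pair[r.pair_id] = {}
            order.append(r.pair_id)
        by_pair[r.pair_id][r.mate_index] = r
    with open(path, "w") as fh:
        for pid in order:
            mates = by_pair[pid]
            for mi in (1, 2):
                r = mates[mi]
                qual = r.quality if r.quality is not None else "I" * len(r.sequence)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")


def read_fasta(path: str | os.PathLike, label: str | None = None) -> ContigSet:
    """Read FASTA into a :class:`ContigSet`.

    The header token before the first whitespace becomes the contig id;
    sequence lines are concatenated and upper-cased.  Duplicate ids and
    characters outside {A,C,G,T,N} are format errors.
    """
    contigs: list[Contig] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        seq = str(rec.seq)
        bad = set(seq) - VALID_CHARS
        if bad:
            raise FormatError(
                f"record {rec.id!r} contains non-DNA characters {sorted(bad)!r}"
            )
        contigs.append(Contig(id=rec.id, sequence=seq.upper()))
    return ContigSet(contigs=contigs, label=label or os.path.basename(str(path)))


def write_fasta(
    contigs: ContigSet | Iterable[Contig],
    path: str | os.PathLike,
    line_width: int = 60,
) -> None:
    """Write contigs as multi-line FASTA; round-trips exactly via read_fasta."""
    if line_width < 1:
        raise ValueError("line_width must be >= 1")
    with open(path, "w") as fh:
        for c in contigs:
            fh.write(f">{c.id}\n")
            for i in range(0, len(c.sequence), line_width):
                fh.write(c.sequence[i : i + line_width] + "\n")


def pair_up(reads: Iterable[Read]) -> dict[str, tuple[Read, Read]]:
    """Group reads into (mate1, mate2) tuples keyed by pair_id.

    Raises :class:`PairingError` if any pair is incomplete or duplicated.
    """
    acc: dict[str, dict[int, Read]] = {}
    for r in reads:
        slot = acc.setdefault(r.pair_id, {})
        if r.mate_index in slot:
            raise PairingError(f"duplicate mate {r.mate_index} for pair {r.pair_id!r}")
        slot[r.mate_index] = r
    out: dict[str, tuple[Read, Read]] = {}
    for pid, mates in acc.items():
        if set(mates) != {1, 2}:
            raise PairingError(f"pair {pid!r} is missing a mate")
        out[pid] = (mates[1], mates[2])
    return out
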