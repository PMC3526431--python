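"""Small shared DNA helpers: reverse complement, canonical k-mers, k-mer iteration.

All sequences are plain upper-case Python strings over {A,C,G,T,N}.  Any k-mer
or word containing N is never indexed anywhere in the package, so helpers that
enumerate k-mers skip N-containing windows.
"""

from __future__ import annotations

from typing import Iterator

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

VALID_CHARS = frozenset("ACGTNacgtn")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(seq: str) -> str:
    """Lexicographic minimum of a sequence and its reverse complement."""
    rc = revcomp(seq)
    return seq if seq <= rc else rc


def iter_kmers(seq: str, k: int, step: int = 1) -> Iterator[tuple[int, str]]:
    """Yield (position, k-mer) for windows starting at 0, step, 2*step, ...

    Windows containing N are skipped.  A sequence shorter than k yields
    nothing.
    """
    n = len(seq)
    if n < k:
        return
    for i in range(0, n - k + 1, step):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        yield i, kmer


def count_mismatches(a: str, b: str, limit: int | None = None) -> int:
    """Hamming distance between equal-length strings, with optional early exit.

    When ``limit`` is given, returns ``limit + 1`` as soon as the count
    exceeds it (the exact value beyond the limit is not needed by callers).
    """
    if a == b:
        return 0
    mm = 0
    if limit is None:
        for x, y in zip(a, b):
            if x != y:
                mm += 1
        return mm
    for x, y in zip(a, b):
        if x != y:
            mm += 1
            if mm > limit:
                return mm
    return mm
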