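"""Exact maximal repetitions (runs) in short reads and canonical STR motif classes.

A *run* is a substring whose minimal period p is at most half its length
(i.e. it contains at least two full copies of its period) and which cannot
be extended by one position in either direction while keeping period p.
Runs are the natural unit for exact short-tandem-repeat content in a read:
every repeated tract is covered by exactly one run with that tract's
minimal period.

Motifs are reported as *canonical classes*: the lexicographically smallest
string among all cyclic rotations of the motif's primitive root and of its
reverse complement.  This collapses e.g. CAG, AGC, GCA, CTG, TGC and GCT
into the single class AGC, matching how STR disease loci are conventionally
grouped (the CAG/CTG class is "AGC", the GAA/TTC class is "AAG").
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import List

__all__ = [
    "RepeatRun",
    "find_runs",
    "canonical_motif",
    "primitive_root",
    "reverse_complement",
    "enumerate_motif_classes",
    "scan_read",
    "DEFAULT_MIN_TRACT",
    "DEFAULT_MAX_MOTIF_LEN",
]

#: Minimum tract length (nt) recorded by default; suppresses ubiquitous
#: very short dinucleotide noise without affecting scoring windows.
DEFAULT_MIN_TRACT = 9

#: Canonical motif lengths analysed by default (STRs are 1-6 nt motifs).
DEFAULT_MAX_MOTIF_LEN = 6

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

_VALID_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class RepeatRun:
    """One exact maximal repetition within a read.

    Coordinates are 0-based, half-open.  ``purity`` is the fraction of
    positions matching the periodic extension of ``motif``; exact detection
    implies 1.0, the field is kept for interoperability with output formats
    that allow approximate repeats.
    """

    start: int
    end: int
    period: int
    motif: str
    canonical_motif: str
    tract_length: int
    purity: float = 1.0

    def __post_init__(self) -> None:
        if self.tract_length != self.end - self.start:
            raise ValueError("tract_length must equal end - start")
        if self.tract_length < 2 * self.period:
            raise ValueError("a run must contain at least two full periods")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a sequence over {A,C,G,T}."""
    return seq.translate(_COMPLEMENT)[::-1]


def _minimal_period(s: str) -> int:
    # Smallest period = length - longest proper border (KMP failure function).
    n = len(s)
    fail = [0] * n
    k = 0
    for i in range(1, n):
        while k and s[i] != s[k]:
            k = fail[k - 1]
        if s[i] == s[k]:
            k += 1
        fail[i] = k
    return n - fail[n - 1]


def find_runs(sequence: str, min_tract: int = DEFAULT_MIN_TRACT) -> List[RepeatRun]:
    """Find all exact maximal repetitions in ``sequence``.

    Returns every maximal repetition with exponent >= 2 and
    ``tract_length >= min_tract``, each reported once with its minimal
    period, sorted by ``(start, period)``.  Positions holding a base other
    than A/C/G/T (i.e. N) belong to no run.

    Parameters
    ----------
    sequence
        Non-empty nucleotide string.
    min_tract
        Minimum tract length (nt) to report; must be >= 2.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    if min_tract < 2:
        raise ValueError("min_tract must be >= 2")
    s = sequence
    n = len(s)
    valid = [c in _VALID_BASES for c in s]
    runs: List[RepeatRun] = []
    for p in range(1, n // 2 + 1):
        i = 0
        limit = n - p
        while i < limit:
            if valid[i] and valid[i + p] and s[i] == s[i + p]:
                k = i + 1
                while k < limit and valid[k + p] and s[k] == s[k + p]:
                    k += 1
                # positions i..k-1 match at lag p -> candidate run [i, k+p)
                end = k + p
                tract = end - i
                if tract >= 2 * p and tract >= min_tract:
                    sub = s[i:end]
                    if _minimal_period(sub) == p:
                        motif = sub[:p]
                        runs.append(
                            RepeatRun(
                                start=i,
                                end=end,
                                period=p,
                                motif=motif,
                                canonical_motif=canonical_motif(motif),
                                tract_length=tract,
                                purity=1.0,
                            )
                        )
                i = k + 1
            else:
                i += 1
    runs.sort(key=lambda r: (r.start, r.period))
    return runs


def primitive_root(motif: str) -> str:
    """Shortest string of which ``motif`` is a whole-number power."""
    n = len(motif)
    for d in range(1, n + 1):
        if n % d == 0 and motif == motif[:d] * (n // d):
            return motif[:d]
    raise AssertionError("unreachable")


def canonical_motif(motif: str) -> str:
    """Canonical representative of a motif's rotation/reverse-complement class.

    The motif is first reduced to its primitive root; the canonical form is
    then the lexicographically smallest string (A < C < G < T) among all
    cyclic rotations of the root and of its reverse complement.

    >>> canonical_motif("CTG")
    'AGC'
    >>> canonical_motif("GAA")
    'AAG'
    >>> canonical_motif("ATAT")
    'AT'
    """
    if not motif:
        raise ValueError("motif must be non-empty")
    if not set(motif) <= _VALID_BASES:
        raise ValueError(f"motif contains non-ACGT characters: {motif!r}")
    root = primitive_root(motif)
    rc = reverse_complement(root)
    k = len(root)
    candidates = [root[i:] + root[:i] for i in range(k)]
    candidates += [rc[i:] + rc[:i] for i in range(k)]
    return min(candidates)


def enumerate_motif_classes(k_min: int, k_max: int) -> List[str]:
    """All distinct canonical motif classes with canonical length in [k_min, k_max].

    Counts per length are fixed combinatorial constants, e.g. 2 monomer
    classes (A, C), 10 trimer classes and 102 pentamer classes.
    """
    if not (1 <= k_min <= k_max):
        raise ValueError("require 1 <= k_min <= k_max")
    if k_max > 6:
        raise ValueError("motif classes above length 6 are not enumerated by default")
    classes = set()
    for k in range(k_min, k_max + 1):
        for tup in itertools.product("ACGT", repeat=k):
            motif = "".join(tup)
            if len(primitive_root(motif)) != k:
                continue  # collapses to a shorter class
            classes.add(canonical_motif(motif))
    return sorted(classes)


def scan_read(read, table, min_tract: int = DEFAULT_MIN_TRACT) -> List[RepeatRun]:
    """Complexity-filter a read and, if it passes, detect its runs.

    Returns ``[]`` without invoking the repeat detector when the read's
    compression ratio exceeds the read-length-dependent threshold in
    ``table``; otherwise returns :func:`find_runs` output (motifs are
    canonicalised by construction).
    """
    from . import complexity  # local import to avoid a cycle at module load

    measurement = complexity.compression_ratio(read.sequence)
    if not complexity.is_candidate(measurement, read.length, table):
        return []
    return find_runs(read.sequence, min_tract=min_tract)
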