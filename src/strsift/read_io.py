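"""Streaming read input: FASTA/FASTQ (optionally gzipped) and SAM text.

Reads are normalised to uppercase over the alphabet {A,C,G,T,N} (any other
character maps to N) and may be trimmed to a uniform length so that samples
sequenced at mixed read lengths can be compared.  Per-file library
statistics (library size ``n`` and modal read length ``j``) are accumulated
while streaming, because downstream information scores are normalised by
the total number of reads, not just the reads that carry repeats.
"""

from __future__ import annotations

import gzip
import io
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterator, Optional, Sequence, Tuple

__all__ = [
    "ReadRecord",
    "LibraryStats",
    "ReadParseError",
    "stream_reads",
    "choose_common_length",
    "write_fasta",
]

_NORMALISE = str.maketrans(
    "acgtn" + "".join(chr(c) for c in range(256) if chr(c).upper() not in "ACGTN"),
    "ACGTN" + "N" * len([c for c in range(256) if chr(c).upper() not in "ACGTN"]),
)


class ReadParseError(ValueError):
    """A sequence file record could not be parsed."""


@dataclass(frozen=True)
class ReadRecord:
    """One sequencing read after normalisation and optional trimming."""

    read_id: str
    sequence: str

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class LibraryStats:
    """Library size ``n`` and post-trim read-length histogram of one input."""

    n_reads: int = 0
    read_length_histogram: Counter = field(default_factory=Counter)

    @property
    def read_length_mode(self) -> int:
        """Most common post-trim read length ``j`` (smallest on ties)."""
        if not self.read_length_histogram:
            raise ValueError("empty library has no modal read length")
        best = max(self.read_length_histogram.values())
        return min(l for l, c in self.read_length_histogram.items() if c == best)

    def add(self, length: int) -> None:
        self.n_reads += 1
        self.read_length_histogram[length] += 1


def _normalise(seq: str) -> str:
    return seq.translate(_NORMALISE)


def _open_maybe_gzip(path) -> IO[str]:
    # gzip detected by magic bytes, not extension
    raw = open(path, "rb")
    magic = raw.read(2)
    raw.seek(0)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.GzipFile(fileobj=raw), encoding="ascii")
    return io.TextIOWrapper(raw, encoding="ascii")


def _sniff_format(path) -> str:
    with _open_maybe_gzip(path) as handle:
        for line in handle:
            if line.strip():
                if line.startswith(">"):
                    return "fasta"
                if line.startswith("@"):
                    return "fastq"
                raise ReadParseError(
                    f"{path}: cannot auto-detect format from leading character "
                    f"{line[0]!r}; pass format explicitly"
                )
    return "fasta"  # empty file; format irrelevant


def _iter_fastq(handle: IO[str], path) -> Iterator[Tuple[str, str]]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    records = FastqGeneralIterator(handle)
    index = 0
    while True:
        try:
            title, seq, _qual = next(records)
        except StopIteration:
            return
        except ValueError as exc:  # truncated record, marker or length mismatch
            raise ReadParseError(
                f"{path}: malformed FASTQ record at index {index}: {exc}"
            ) from exc
        yield title.split()[0] if title.split() else "", seq
        index += 1


def _iter_fasta(handle: IO[str], path) -> Iterator[Tuple[str, str]]:
    from Bio import SeqIO

    for record in SeqIO.parse(handle, "fasta"):
        yield record.id, str(record.seq)


def _iter_sam(handle: IO[str], path) -> Iterator[Tuple[str, str]]:
    # SAM text: consume only QNAME and SEQ (column 10); '*' sequences skipped.
    index = 0
    for line in handle:
        if line.startswith("@") or not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 11:
            raise ReadParseError(f"{path}: malformed SAM line at record index {index}")
        index += 1
        if fields[9] == "*":
            continue
        yield fields[0], fields[9]


_PARSERS = {"fastq": _iter_fastq, "fasta": _iter_fasta, "sam": _iter_sam}


def stream_reads(
    path,
    format: str = "auto",
    trim_to: Optional[int] = None,
    stats: Optional[LibraryStats] = None,
) -> Tuple[Iterator[ReadRecord], LibraryStats]:
    """Stream normalised reads from a FASTA/FASTQ/SAM file.

    Returns ``(iterator, stats)``.  ``stats`` is filled in *while the
    iterator is consumed*; it reflects post-trim lengths and counts every
    read exactly once.  Reads longer than ``trim_to`` are truncated to
    their first ``trim_to`` nt; shorter reads are yielded untrimmed (they
    appear under their own length in the histogram).  Gzip input is
    detected by magic bytes.  An empty file yields no reads and
    ``n_reads == 0`` (not an error).

    Pass an existing ``stats`` object to accumulate a library size across
    several files of one sample (e.g. the two mates of a paired-end run).
    """
    path = Path(path)
    if trim_to is not None and trim_to < 1:
        raise ValueError("trim_to must be >= 1")
    if format == "auto":
        format = _sniff_format(path)
    if format not in _PARSERS:
        raise ValueError(f"unknown format {format!r}")
    if stats is None:
        stats = LibraryStats()

    def _generator() -> Iterator[ReadRecord]:
        with _open_maybe_gzip(path) as handle:
            for read_id, raw_seq in _PARSERS[format](handle, path):
                seq = _normalise(raw_seq)
                if trim_to is not None and len(seq) > trim_to:
                    seq = seq[:trim_to]
                stats.add(len(seq))
                yield ReadRecord(read_id=read_id, sequence=seq)

    return _generator(), stats


def choose_common_length(stats_list: Sequence[LibraryStats]) -> int:
    """Uniform trim length for a mixed-read-length cohort.

    Returns the minimum of the per-sample modal read lengths; re-processing
    every sample with ``trim_to`` set to this value makes information-score
    windows comparable across samples (trimming longer reads is analogous
    to downsampling those experiments).
    """
    if not stats_list:
        raise ValueError("stats_list must be non-empty")
    for stats in stats_list:
        if stats.n_reads == 0:
            raise ValueError("every sample must contain at least one read")
    return min(stats.read_length_mode for stats in stats_list)


def write_fasta(path, reads, gzipped: bool = False) -> int:
    """Write reads to a (optionally gzip-compressed) FASTA file; returns count."""
    opener = gzip.open if gzipped else open
    n = 0
    with opener(path, "wt") as handle:
        for read in reads:
            handle.write(f">{read.read_id}\n{read.sequence}\n")
            n += 1
    return n
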