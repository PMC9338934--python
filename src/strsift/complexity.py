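"""Compression-based read complexity and read-length-dependent thresholds.

Repetitive sequence is more compressible than non-repetitive sequence, so
the ratio C of DEFLATE-compressed size to raw size of a read's nucleotide
string separates repeat-bearing reads from background at a read-length-
dependent threshold.  C is defined over the **raw DEFLATE stream** (no
gzip/zlib header or trailer) at the compressor's fastest setting; the
convention is pinned in :data:`DEFLATE_CONVENTION` and recorded in output
metadata, because wrapper bytes shift C additively and differ across
containers.

Thresholds are calibrated by simulation: labelled repeat-bearing and
background reads are generated at each read length and the threshold
maximising Youden's J (sensitivity + specificity - 1) is chosen.  A
built-in table calibrated under the uniform background ships with the
package; users can recalibrate for their own read lengths and base
compositions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "CompressionMeasurement",
    "ThresholdTable",
    "ThresholdLookupError",
    "CalibrationError",
    "compression_ratio",
    "is_candidate",
    "calibrate_thresholds",
    "DEFLATE_CONVENTION",
    "COMPRESSION_LEVEL",
]

#: Fastest zlib setting (Z_BEST_SPEED).
COMPRESSION_LEVEL = 1

#: Container convention for C: raw DEFLATE, no header/trailer, level 1.
DEFLATE_CONVENTION = "raw-deflate-wbits=-15-level=1"


class ThresholdLookupError(KeyError):
    """A read length has no threshold entry; calibration is required."""


class CalibrationError(RuntimeError):
    """Threshold calibration failed (e.g. inseparable class distributions)."""


@dataclass(frozen=True)
class CompressionMeasurement:
    """Compression ratio C of one read (output bytes / input bytes)."""

    c_ratio: float
    input_bytes: int
    output_bytes: int


@dataclass
class ThresholdTable:
    """Read length -> threshold on C, with calibration provenance.

    ``entries`` maps read length L (nt) to the threshold t_L; a read of
    length L is a repeat candidate iff its C <= t_L.  ``metrics`` holds the
    sensitivity/specificity achieved on the calibration data, when known.
    Lookup of an absent read length fails loudly; no silent interpolation.
    """

    entries: Dict[int, float]
    provenance: str = "calibrated"
    background: str = "uniform"
    seed: Optional[int] = None
    metrics: Dict[int, Tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for length, t in self.entries.items():
            if t <= 0:
                raise ValueError(f"threshold for L={length} must be positive")

    def threshold_for(self, read_length: int) -> float:
        try:
            return self.entries[read_length]
        except KeyError:
            raise ThresholdLookupError(
                f"no threshold for read length {read_length}; available lengths "
                f"are {sorted(self.entries)}; run calibration for this length"
            ) from None

    def to_tsv(self, path) -> None:
        with open(path, "w") as handle:
            handle.write(f"# provenance: {self.provenance}\n")
            handle.write(f"# convention: {DEFLATE_CONVENTION}\n")
            handle.write("read_length\tthreshold\tsensitivity\tspecificity\tbackground\tseed\n")
            for length in sorted(self.entries):
                sens, spec = self.metrics.get(length, (float("nan"), float("nan")))
                handle.write(
                    f"{length}\t{self.entries[length]:.6f}\t{sens:.4f}\t{spec:.4f}"
                    f"\t{self.background}\t{'' if self.seed is None else self.seed}\n"
                )

    @classmethod
    def from_tsv(cls, path) -> "ThresholdTable":
        entries: Dict[int, float] = {}
        metrics: Dict[int, Tuple[float, float]] = {}
        provenance = "calibrated"
        background = "uniform"
        seed: Optional[int] = None
        with open(path) as handle:
            for line in handle:
                line = line.strip()
                if not line:
                    continue
                if line.startswith("#"):
                    if line.startswith("# provenance:"):
                        provenance = line.split(":", 1)[1].strip()
                    continue
                if line.startswith("read_length"):
                    continue
                fields = line.split("\t")
                length = int(fields[0])
                entries[length] = float(fields[1])
                if len(fields) >= 4:
                    metrics[length] = (float(fields[2]), float(fields[3]))
                if len(fields) >= 5:
                    background = fields[4]
                if len(fields) >= 6 and fields[5]:
                    seed = int(fields[5])
        return cls(
            entries=entries,
            provenance=provenance,
            background=background,
            seed=seed,
            metrics=metrics,
        )

    @classmethod
    def builtin(cls) -> "ThresholdTable":
        """Built-in table calibrated under the uniform background."""
        with resources.as_file(
            resources.files("strsift.data").joinpath("thresholds_builtin.tsv")
        ) as path:
            table = cls.from_tsv(path)
        table.provenance = "builtin"
        return table


def compression_ratio(sequence: str) -> CompressionMeasurement:
    """Compression ratio C of a read's nucleotide string.

    C = compressed bytes / raw bytes under the pinned raw-DEFLATE
    convention at the fastest compression level; deterministic for a given
    sequence.  One input byte per nucleotide character.
    """
    if not sequence:
        raise ValueError("compression ratio is undefined for an empty sequence")
    compressor = zlib.compressobj(COMPRESSION_LEVEL, zlib.DEFLATED, -15)
    data = sequence.encode("ascii")
    out = compressor.compress(data) + compressor.flush()
    return CompressionMeasurement(
        c_ratio=len(out) / len(data),
        input_bytes=len(data),
        output_bytes=len(out),
    )


def is_candidate(
    measurement: CompressionMeasurement, read_length: int, table: ThresholdTable
) -> bool:
    """True iff the read is compressible enough to be a repeat candidate.

    The boundary is inclusive: ``C <= t_L`` passes (favouring sensitivity;
    a false positive merely reaches the repeat detector).
    """
    return measurement.c_ratio <= table.threshold_for(read_length)


def _youden_threshold(
    c_repeat: np.ndarray, c_background: np.ndarray
) -> Tuple[float, float, float]:
    """Threshold on C maximising Youden's J, with achieved sens/spec.

    Candidates are the observed C values.  Ties on J are broken in favour
    of higher sensitivity, then the smaller threshold.
    """
    candidates = np.unique(np.concatenate([c_repeat, c_background]))
    # classification rule: candidate iff C <= t
    sens = np.mean(c_repeat[:, None] <= candidates[None, :], axis=0)
    spec = np.mean(c_background[:, None] > candidates[None, :], axis=0)
    j = sens + spec - 1.0
    best_j = j.max()
    if best_j <= 0:
        raise CalibrationError(
            "repeat and background C distributions are inseparable (Youden's "
            "J <= 0 at every candidate threshold); check the simulation "
            "configuration and labels"
        )
    mask = j == best_j
    order = np.lexsort((candidates[mask], -sens[mask]))
    idx = np.flatnonzero(mask)[order[0]]
    return float(candidates[idx]), float(sens[idx]), float(spec[idx])


def calibrate_thresholds(
    read_lengths: Iterable[int],
    sim_config,
    n_reads_per_class: int = 2000,
    seed: int = 0,
) -> ThresholdTable:
    """Calibrate C thresholds by simulation at each requested read length.

    For each read length, ``n_reads_per_class`` repeat-informative reads
    (>= 45 nt of repetitive sequence, STR motifs 1-6 nt) and the same
    number of background reads are generated under ``sim_config``'s base
    composition and error model; the threshold maximising Youden's J on
    the observed C values is recorded together with the sensitivity and
    specificity it achieves on the calibration data.

    Deterministic for a fixed ``seed``; the same seed returns an identical
    table.
    """
    from . import simulate  # deferred: simulate imports this module

    if n_reads_per_class < 1:
        raise ValueError("n_reads_per_class must be >= 1")
    read_lengths = sorted(set(int(l) for l in read_lengths))
    entries: Dict[int, float] = {}
    metrics: Dict[int, Tuple[float, float]] = {}
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(read_lengths))
    for child, length in zip(children, read_lengths):
        rng = np.random.default_rng(child)
        config = sim_config.with_read_length(length)
        c_rep = np.empty(n_reads_per_class)
        c_bg = np.empty(n_reads_per_class)
        for i, (read, label) in enumerate(
            simulate.labelled_repeat_reads(config, n_reads_per_class, rng)
        ):
            assert label
            c_rep[i] = compression_ratio(read.sequence).c_ratio
        for i in range(n_reads_per_class):
            c_bg[i] = compression_ratio(
                simulate.background_read(config, rng).sequence
            ).c_ratio
        threshold, sens, spec = _youden_threshold(c_rep, c_bg)
        entries[length] = threshold
        metrics[length] = (sens, spec)
    return ThresholdTable(
        entries=entries,
        provenance="calibrated",
        background=sim_config.background,
        seed=seed,
        metrics=metrics,
    )
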