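"""Synthetic read, locus and cohort generation.

Everything the pipeline consumes can be simulated here: pseudorandom
background reads under single-nucleotide composition models, reads
carrying (im)pure repeat tracts, read sets sampled from a synthetic
expansion locus, and whole case/control cohorts written as FASTA plus a
manifest.  All generators are deterministic functions of their
configuration and seed.

Ground truth for the complexity filter follows the *informative read*
convention: a read is repeat-informative iff it contains at least
:data:`INFORMATIVE_MIN_NT` (45) nucleotides of repetitive sequence.

Base-composition presets are single-nucleotide frequency models
(p_A, p_C, p_G, p_T):

``uniform``
    each nucleotide equiprobable;
``human``
    genome-wide human composition (~41% GC);
``gc_rich``
    a GC-rich bacterial genome (~72% GC, e.g. *Streptomyces coelicolor*);
``at_rich``
    AT-rich intergenic sequence (~86% AT, e.g. *Plasmodium falciparum*
    intergenic regions).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, List, Optional, Sequence, Tuple

import numpy as np

from .read_io import ReadRecord, write_fasta
from . import repeats

__all__ = [
    "SimConfig",
    "SimulatedLocus",
    "ClassifierMetrics",
    "BACKGROUND_PRESETS",
    "INFORMATIVE_MIN_NT",
    "background_read",
    "background_reads",
    "repeat_read",
    "labelled_repeat_reads",
    "make_locus",
    "simulate_locus_reads",
    "simulate_cohort",
    "evaluate_classifier",
]

#: Minimum repetitive nucleotides for a read to count as repeat-informative.
INFORMATIVE_MIN_NT = 45

BACKGROUND_PRESETS = {
    "uniform": (0.25, 0.25, 0.25, 0.25),
    "human": (0.295, 0.205, 0.205, 0.295),
    "gc_rich": (0.14, 0.36, 0.36, 0.14),
    "at_rich": (0.43, 0.07, 0.07, 0.43),
}

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the read simulator.

    Parameters
    ----------
    background
        Name of a composition preset, or ``"custom"`` with explicit
        ``probs``.
    probs
        Nucleotide probabilities (p_A, p_C, p_G, p_T); must sum to 1.
    read_length
        Simulated read length in nt.
    error_rate
        Per-base substitution probability (no indels).
    motif_change_prob
        Per-motif-copy probability of one random substitution within that
        copy, producing impure repeat tracts.
    seed
        Default seed for generators called without an explicit RNG.
    """

    background: str = "uniform"
    probs: Optional[Tuple[float, float, float, float]] = None
    read_length: int = 150
    error_rate: float = 0.0
    motif_change_prob: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.probs is None:
            if self.background not in BACKGROUND_PRESETS:
                raise ValueError(
                    f"unknown background {self.background!r}; presets are "
                    f"{sorted(BACKGROUND_PRESETS)} (or pass probs with "
                    f"background='custom')"
                )
            object.__setattr__(self, "probs", BACKGROUND_PRESETS[self.background])
        if abs(sum(self.probs) - 1.0) > 1e-9:
            raise ValueError("nucleotide probabilities must sum to 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if not (0 <= self.motif_change_prob < 1):
            raise ValueError("motif_change_prob must be in [0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")

    def with_read_length(self, read_length: int) -> "SimConfig":
        return replace(self, read_length=read_length)

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class SimulatedLocus:
    """A synthetic expansion locus: repeat tract between non-repetitive flanks."""

    flank5: str
    flank3: str
    motif: str
    n_copies: int

    @property
    def tract(self) -> str:
        return self.motif * self.n_copies

    @property
    def insert_start(self) -> int:
        return len(self.flank5)

    @property
    def sequence(self) -> str:
        return self.flank5 + self.tract + self.flank3


@dataclass(frozen=True)
class ClassifierMetrics:
    """Confusion-matrix summary of the complexity filter vs ground truth."""

    sensitivity: float
    specificity: float
    tp: int
    fn: int
    tn: int
    fp: int


def _draw_bases(n: int, probs, rng: np.random.Generator) -> np.ndarray:
    return rng.choice(_BASES, size=n, p=np.asarray(probs, dtype=float))


def _apply_errors(bases: np.ndarray, error_rate: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each base, independently with prob error_rate, by a *different* base."""
    if error_rate <= 0:
        return bases
    hit = rng.random(bases.size) < error_rate
    if hit.any():
        idx = np.flatnonzero(hit)
        # shift by 1..3 in base order to guarantee a change
        current = np.searchsorted(_BASES, bases[idx])
        shift = rng.integers(1, 4, size=idx.size)
        bases = bases.copy()
        bases[idx] = _BASES[(current + shift) % 4]
    return bases


def background_read(
    config: SimConfig, rng: Optional[np.random.Generator] = None, read_id: str = "bg"
) -> ReadRecord:
    """One pseudorandom read of i.i.d. nucleotides from the configured composition."""
    if rng is None:
        rng = config.rng()
    bases = _draw_bases(config.read_length, config.probs, rng)
    return ReadRecord(read_id=read_id, sequence="".join(bases))


def background_reads(
    config: SimConfig, n: int, rng: Optional[np.random.Generator] = None
) -> Iterator[ReadRecord]:
    """Deterministic stream of ``n`` background reads."""
    if rng is None:
        rng = config.rng()
    for i in range(n):
        yield background_read(config, rng, read_id=f"bg_{i}")


def repeat_read(
    config: SimConfig,
    motif: str,
    repeat_nt: int,
    offset: Optional[int] = None,
    rng: Optional[np.random.Generator] = None,
    read_id: str = "rep",
) -> Tuple[ReadRecord, bool]:
    """A background read with ``repeat_nt`` nt replaced by a periodic motif tract.

    The tract occupies positions ``[offset, offset + repeat_nt)`` (random
    valid offset if None).  Each full motif copy is independently altered
    (one random substitution within the copy) with probability
    ``motif_change_prob``; every base of the read is then substituted with
    probability ``error_rate``.  The boolean label is the informative-read
    ground truth, ``repeat_nt >= 45``.
    """
    if rng is None:
        rng = config.rng()
    L = config.read_length
    if not (1 <= repeat_nt <= L):
        raise ValueError("repeat_nt must be in [1, read_length]")
    if offset is None:
        offset = int(rng.integers(0, L - repeat_nt + 1))
    if not (0 <= offset <= L - repeat_nt):
        raise ValueError("offset must satisfy 0 <= offset <= read_length - repeat_nt")
    bases = _draw_bases(L, config.probs, rng)
    k = len(motif)
    n_full = repeat_nt // k
    tract = np.array(list((motif * (repeat_nt // k + 1))[:repeat_nt]))
    if config.motif_change_prob > 0 and n_full > 0:
        changed = rng.random(n_full) < config.motif_change_prob
        for copy_idx in np.flatnonzero(changed):
            pos = copy_idx * k + int(rng.integers(0, k))
            current = int(np.searchsorted(_BASES, tract[pos]))
            tract[pos] = _BASES[(current + int(rng.integers(1, 4))) % 4]
    bases[offset : offset + repeat_nt] = tract
    bases = _apply_errors(bases, config.error_rate, rng)
    return (
        ReadRecord(read_id=read_id, sequence="".join(bases)),
        repeat_nt >= INFORMATIVE_MIN_NT,
    )


#: Largest motif length sampled when simulating repeat-bearing reads.
MAX_SIM_MOTIF_LEN = 15


def _random_motif(rng: np.random.Generator, max_len: int = MAX_SIM_MOTIF_LEN) -> str:
    """A random primitive motif of length 1..max_len."""
    while True:
        k = int(rng.integers(1, max_len + 1))
        motif = "".join(rng.choice(_BASES, size=k))
        if repeats.primitive_root(motif) == motif:
            return motif


def labelled_repeat_reads(
    config: SimConfig, n: int, rng: Optional[np.random.Generator] = None
) -> Iterator[Tuple[ReadRecord, bool]]:
    """``n`` repeat-informative reads with random repeat motifs (1-15 nt).

    Tract lengths are uniform over [45, read_length] so every read meets
    the informative-read labelling; used for threshold calibration and
    classifier evaluation.
    """
    if rng is None:
        rng = config.rng()
    lo = min(INFORMATIVE_MIN_NT, config.read_length)
    for i in range(n):
        motif = _random_motif(rng)
        repeat_nt = int(rng.integers(lo, config.read_length + 1))
        yield repeat_read(config, motif, repeat_nt, rng=rng, read_id=f"rep_{i}")


def make_locus(
    config: SimConfig,
    motif: str,
    n_copies: int,
    flank_len: int = 2500,
    rng: Optional[np.random.Generator] = None,
    max_flank_tract: int = 14,
    max_tries: int = 200,
) -> SimulatedLocus:
    """Assemble a synthetic expansion locus with verified non-repetitive flanks.

    Flanks are background sequence rejection-sampled until the package's
    own run detector reports no run with tract length > ``max_flank_tract``
    nt, emulating repeat-masked genomic flanks.
    """
    if rng is None:
        rng = config.rng()

    def _flank() -> str:
        for _ in range(max_tries):
            seq = "".join(_draw_bases(flank_len, config.probs, rng))
            if not repeats.find_runs(seq, min_tract=max_flank_tract + 1):
                return seq
        raise RuntimeError(
            f"could not sample a repeat-free flank of {flank_len} nt in "
            f"{max_tries} tries; relax max_flank_tract or shorten the flank"
        )

    return SimulatedLocus(flank5=_flank(), flank3=_flank(), motif=motif, n_copies=n_copies)


def simulate_locus_reads(
    locus: SimulatedLocus,
    depth: float,
    config: SimConfig,
    rng: Optional[np.random.Generator] = None,
) -> List[Tuple[ReadRecord, bool]]:
    """Uniformly sample reads from an assembled locus at the given coverage.

    Read count is ``round(depth * locus_length / read_length)``; start
    positions are uniform over valid positions; each read is labelled
    informative iff it overlaps the repeat tract by at least 45 nt.
    Substitution errors are applied per read.
    """
    if rng is None:
        rng = config.rng()
    if depth <= 0:
        raise ValueError("depth must be positive")
    seq = locus.sequence
    L = config.read_length
    if len(seq) < L:
        raise ValueError("locus must be at least one read length long")
    n_reads = int(round(depth * len(seq) / L))
    tract_start = locus.insert_start
    tract_end = tract_start + len(locus.tract)
    out: List[Tuple[ReadRecord, bool]] = []
    starts = rng.integers(0, len(seq) - L + 1, size=n_reads)
    for i, start in enumerate(starts):
        start = int(start)
        bases = np.array(list(seq[start : start + L]))
        bases = _apply_errors(bases, config.error_rate, rng)
        overlap = min(start + L, tract_end) - max(start, tract_start)
        out.append(
            (
                ReadRecord(read_id=f"locus_{i}", sequence="".join(bases)),
                overlap >= INFORMATIVE_MIN_NT,
            )
        )
    return out


def simulate_cohort(
    n_cases: int,
    n_controls: int,
    motif: str,
    case_repeat_nt: int,
    reads_per_sample: int,
    config: SimConfig,
    out_dir,
    n_repeat_reads: int = 25,
) -> Path:
    """Write a synthetic case/control cohort as FASTA files plus a manifest.

    Controls are pure background read sets.  Cases carry, in addition to
    background reads, ``n_repeat_reads`` reads sampled across an expansion
    tract of ``case_repeat_nt`` nt of ``motif`` (a read's repetitive span
    is ``min(case_repeat_nt, read_length)``; tracts shorter than the read
    are placed at a random offset).  Total reads per sample is
    ``reads_per_sample`` for every sample.  Returns the manifest path;
    byte-identical output for a fixed config seed.
    """
    if min(n_cases, n_controls, reads_per_sample) < 1:
        raise ValueError("counts must be >= 1")
    if n_repeat_reads > reads_per_sample:
        raise ValueError("n_repeat_reads cannot exceed reads_per_sample")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = config.rng()
    span = min(case_repeat_nt, config.read_length)
    rows = []
    for group, count in (("case", n_cases), ("control", n_controls)):
        for s in range(count):
            sample_id = f"{group}_{s:02d}"
            path = out_dir / f"{sample_id}.fasta"
            reads: List[ReadRecord] = []
            n_bg = reads_per_sample
            if group == "case" and span >= 1:
                n_bg -= n_repeat_reads
                for r in range(n_repeat_reads):
                    read, _ = repeat_read(
                        config, motif, span, rng=rng, read_id=f"{sample_id}_rep_{r}"
                    )
                    reads.append(read)
            for r in range(n_bg):
                reads.append(background_read(config, rng, read_id=f"{sample_id}_bg_{r}"))
            write_fasta(path, reads)
            rows.append((sample_id, path.name, group))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as handle:
        handle.write("sample_id\tpath\tlabel\n")
        for sample_id, name, group in rows:
            handle.write(f"{sample_id}\t{name}\t{group}\n")
    return manifest


def evaluate_classifier(
    config: SimConfig,
    table,
    n_per_class: int,
    seed: Optional[int] = None,
    protocol: str = "full",
) -> ClassifierMetrics:
    """Evaluate the complexity filter against the informative-read labelling.

    Two evaluation designs are supported, mirroring the two simulation
    studies the filter is characterised by:

    ``"informative"``
        ``n_per_class`` repeat-informative reads (tract >= 45 nt, always
        labelled positive) versus ``n_per_class`` pure background reads.
        This is the calibration design and measures raw separability of
        the two C distributions.
    ``"full"`` (default)
        ``n_per_class`` repeat-carrying reads with tract lengths uniform
        over [1, read_length] — labelled by the 45-nt rule, so sub-45
        tracts are *negatives* — plus ``n_per_class`` background reads.
        This measures threshold performance against the labelling itself;
        reads whose tract sits just below 45 nt are intrinsically
        confusable, and they occupy a growing share of the negative class
        as reads shorten, which is why specificity degrades at short read
        lengths.
    """
    from . import complexity

    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if protocol not in ("informative", "full"):
        raise ValueError("protocol must be 'informative' or 'full'")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    threshold = table.threshold_for(config.read_length)
    tp = fn = tn = fp = 0

    def _called(read: ReadRecord) -> bool:
        return complexity.compression_ratio(read.sequence).c_ratio <= threshold

    if protocol == "informative":
        repeat_reads: Iterator[Tuple[ReadRecord, bool]] = labelled_repeat_reads(
            config, n_per_class, rng
        )
    else:

        def _full() -> Iterator[Tuple[ReadRecord, bool]]:
            for i in range(n_per_class):
                motif = _random_motif(rng)
                repeat_nt = int(rng.integers(1, config.read_length + 1))
                yield repeat_read(config, motif, repeat_nt, rng=rng, read_id=f"r_{i}")

        repeat_reads = _full()

    for read, label in repeat_reads:
        called = _called(read)
        if label and called:
            tp += 1
        elif label:
            fn += 1
        elif called:
            fp += 1
        else:
            tn += 1
    for _ in range(n_per_class):
        if _called(background_read(config, rng)):
            fp += 1
        else:
            tn += 1
    return ClassifierMetrics(
        sensitivity=tp / (tp + fn),
        specificity=tn / (tn + fp),
        tp=tp,
        fn=fn,
        tn=tn,
        fp=fp,
    )
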