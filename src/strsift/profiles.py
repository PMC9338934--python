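"""Per-sample repeat summaries and per-motif information scores.

Each sample is summarised into, per canonical motif m, a count vector
v = (v_1 ... v_j) where v_l is the number of detected runs of motif m with
tract length exactly l and j is the sample's read length.  The information
score for a motif is

    s_m = ( sum_{i <= l <= j} v_l * l ) / n

with n the library size (total reads processed, candidates or not).  The
default window is j = read length and i = floor(0.75 * j), so only tracts
spanning at least three quarters of a read contribute — the long-tract
signal of a repeat expansion.  Counts are stored raw and divided by n
exactly once, here; this keeps s_m invariant under duplication of every
read (doubling depth doubles every v_l and n, leaving s_m unchanged).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

import pandas as pd

from .read_io import LibraryStats, ReadRecord
from .repeats import DEFAULT_MAX_MOTIF_LEN, RepeatRun

__all__ = [
    "SampleProfile",
    "ScoreVector",
    "CohortMatrix",
    "build_profile",
    "information_scores",
    "assemble_cohort",
    "write_profile",
    "read_profile",
    "read_manifest",
]


@dataclass
class SampleProfile:
    """Per-sample map canonical motif -> sparse tract-length count vector."""

    sample_id: str
    library_size: int
    read_length: int
    counts: Dict[str, Dict[int, int]] = field(default_factory=dict)

    def add_run(self, run: RepeatRun) -> None:
        if run.tract_length > self.read_length:
            raise ValueError(
                f"run tract length {run.tract_length} exceeds read length "
                f"{self.read_length}; re-trim the sample to a uniform length"
            )
        vec = self.counts.setdefault(run.canonical_motif, {})
        vec[run.tract_length] = vec.get(run.tract_length, 0) + 1


@dataclass(frozen=True)
class ScoreVector:
    """Per-sample information scores with the tract-length window used."""

    sample_id: str
    scores: Mapping[str, float]
    window: Tuple[int, int]


@dataclass
class CohortMatrix:
    """Dense samples x motifs information-score matrix with group labels."""

    scores: pd.DataFrame  # index: sample_id, columns: canonical motifs
    labels: pd.Series  # index: sample_id -> group label
    window: Tuple[int, int]

    def group_scores(self, motif: str, label: str) -> pd.Series:
        return self.scores.loc[self.labels == label, motif]


def build_profile(
    runs_by_read: Iterable[Tuple[ReadRecord, List[RepeatRun]]],
    stats: LibraryStats,
    max_motif_len: int = DEFAULT_MAX_MOTIF_LEN,
    sample_id: str = "sample",
    read_length: Optional[int] = None,
) -> SampleProfile:
    """Summarise per-read runs into a sample profile.

    Every run whose canonical motif is at most ``max_motif_len`` nt
    increments exactly one count cell; several runs in one read each
    count.  The library size is the total number of reads in ``stats``
    (not only candidate reads).  ``read_length`` defaults to the modal
    post-trim read length.
    """
    profile = SampleProfile(
        sample_id=sample_id,
        library_size=0,
        read_length=0,
        counts={},
    )
    pending: List[RepeatRun] = []
    for _read, runs in runs_by_read:
        for run in runs:
            if len(run.canonical_motif) <= max_motif_len:
                pending.append(run)
    if stats.n_reads <= 0:
        raise ValueError("library must contain at least one read")
    profile.library_size = stats.n_reads
    profile.read_length = (
        stats.read_length_mode if read_length is None else read_length
    )
    for run in pending:
        profile.add_run(run)
    return profile


def information_scores(
    profile: SampleProfile, i: Optional[int] = None, j: Optional[int] = None
) -> ScoreVector:
    """Information score s_m = (sum_{i<=l<=j} v_l * l) / n per motif.

    Defaults: ``j`` is the read length and ``i = floor(0.75 * j)``.
    Motifs with no counted tract inside the window score 0.
    """
    if j is None:
        j = profile.read_length
    if i is None:
        i = math.floor(0.75 * j)
    if i > j:
        raise ValueError(f"window start i={i} exceeds window end j={j}")
    if not (1 <= i and j <= profile.read_length):
        raise ValueError("require 1 <= i <= j <= read_length")
    n = profile.library_size
    scores = {
        motif: sum(v * l for l, v in vec.items() if i <= l <= j) / n
        for motif, vec in profile.counts.items()
    }
    return ScoreVector(sample_id=profile.sample_id, scores=scores, window=(i, j))


def assemble_cohort(
    score_vectors: Sequence[ScoreVector], labels: Mapping[str, str]
) -> CohortMatrix:
    """Stack per-sample scores into a dense cohort matrix.

    Motifs missing in a sample score 0.  Sample IDs must be unique, every
    sample needs a label, and all score vectors must share one
    tract-length window (samples processed at different read lengths must
    be re-trimmed to a common length first).
    """
    if not score_vectors:
        raise ValueError("no score vectors supplied")
    ids = [sv.sample_id for sv in score_vectors]
    if len(set(ids)) != len(ids):
        dup = sorted({x for x in ids if ids.count(x) > 1})
        raise ValueError(f"duplicate sample_id(s): {dup}")
    windows = {sv.window for sv in score_vectors}
    if len(windows) != 1:
        raise ValueError(
            f"mismatched score windows across samples: {sorted(windows)}; "
            "re-trim all samples to a common read length "
            "(see read_io.choose_common_length) and re-process"
        )
    missing = [sid for sid in ids if sid not in labels]
    if missing:
        raise ValueError(f"samples without labels: {missing}")
    motifs = sorted({m for sv in score_vectors for m in sv.scores})
    frame = pd.DataFrame(
        [[sv.scores.get(m, 0.0) for m in motifs] for sv in score_vectors],
        index=pd.Index(ids, name="sample_id"),
        columns=motifs,
        dtype=float,
    )
    label_series = pd.Series({sid: labels[sid] for sid in ids}, name="label")
    return CohortMatrix(scores=frame, labels=label_series, window=score_vectors[0].window)


def write_profile(profile: SampleProfile, path) -> None:
    """Write a profile as TSV with '#'-prefixed header metadata."""
    with open(path, "w") as handle:
        handle.write(f"#sample_id\t{profile.sample_id}\n")
        handle.write(f"#library_size\t{profile.library_size}\n")
        handle.write(f"#read_length\t{profile.read_length}\n")
        handle.write("motif\ttract_length\tcount\n")
        for motif in sorted(profile.counts):
            for tract in sorted(profile.counts[motif]):
                handle.write(f"{motif}\t{tract}\t{profile.counts[motif][tract]}\n")


def read_profile(path) -> SampleProfile:
    """Read a profile written by :func:`write_profile`."""
    meta: Dict[str, str] = {}
    counts: Dict[str, Dict[int, int]] = {}
    with open(path) as handle:
        for line in handle:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, value = line[1:].partition("\t")
                meta[key] = value
                continue
            if line.startswith("motif\t"):
                continue
            motif, tract, count = line.split("\t")
            counts.setdefault(motif, {})[int(tract)] = int(count)
    for required in ("sample_id", "library_size", "read_length"):
        if required not in meta:
            raise ValueError(f"{path}: profile file missing #{required} header")
    return SampleProfile(
        sample_id=meta["sample_id"],
        library_size=int(meta["library_size"]),
        read_length=int(meta["read_length"]),
        counts=counts,
    )


def read_manifest(path) -> pd.DataFrame:
    """Read a cohort manifest (TSV: sample_id, path, label).

    Relative profile paths are resolved against the manifest's directory.
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "path", "label"}
    if not required <= set(frame.columns):
        raise ValueError(
            f"{path}: manifest must have columns {sorted(required)}, "
            f"found {list(frame.columns)}"
        )
    if frame["sample_id"].duplicated().any():
        dups = frame.loc[frame["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_id(s) in manifest: {dups}")
    frame["path"] = [
        str(p) if Path(p).is_absolute() else str(path.parent / p) for p in frame["path"]
    ]
    return frame
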