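"""One-versus-many outlier detection on motif information scores.

For each motif, a 95% confidence interval for the 95th percentile of the
information score is estimated **in the background (control) cohort only**
by the bias-corrected and accelerated (BCa) bootstrap; query samples whose
score strictly exceeds the interval's upper end are reported as outliers.
Using only unaffected/unascertained backgrounds avoids the contamination
problem of case-resampling schemes that assume a fixed outlier fraction.

The BCa interval can be undefined on degenerate backgrounds (e.g. all
scores identical, so the bootstrap distribution collapses); the estimator
then falls back to the plain percentile bootstrap, and the fallback is
recorded in the result.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .profiles import CohortMatrix

__all__ = [
    "OutlierResult",
    "quantile_ci_bca",
    "call_outliers",
    "DEFAULT_N_BOOT",
    "DEFAULT_QUANTILE",
    "DEFAULT_CONF",
    "MIN_BACKGROUND",
]

DEFAULT_N_BOOT = 9_999
DEFAULT_QUANTILE = 0.95
DEFAULT_CONF = 0.95
MIN_BACKGROUND = 20


@dataclass(frozen=True)
class OutlierResult:
    motif: str
    sample_id: str
    score: float
    background_n: int
    upper_bound: float
    method: str  # "bca" or "percentile"
    is_outlier: bool


def _quantile_statistic(q: float):
    # linear interpolation between order statistics (numpy default), pinned
    def statistic(sample, axis=-1):
        return np.quantile(sample, q, axis=axis)

    return statistic


def quantile_ci_bca(
    background: Sequence[float],
    q: float = DEFAULT_QUANTILE,
    conf: float = DEFAULT_CONF,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> Tuple[float, float, str]:
    """Bootstrap CI for the empirical q-quantile of a background sample.

    Returns ``(lower, upper, method)`` where method is ``"bca"`` or, when
    the BCa bias-correction or acceleration is undefined (degenerate
    bootstrap distribution, zero jackknife variance), ``"percentile"``.
    Deterministic under a fixed seed.
    """
    data = np.asarray(background, dtype=float)
    if data.size < MIN_BACKGROUND:
        raise ValueError(
            f"background has {data.size} samples; at least {MIN_BACKGROUND} are "
            "required for a stable quantile interval (consider percentile-only "
            "mode on a larger background)"
        )
    if not (0 < q < 1) or not (0 < conf < 1):
        raise ValueError("q and conf must lie in (0, 1)")
    statistic = _quantile_statistic(q)
    point = float(statistic(data))
    if np.all(data == data[0]):
        return point, point, "percentile"

    def _run(method: str):
        return stats.bootstrap(
            (data,),
            statistic,
            confidence_level=conf,
            n_resamples=n_boot,
            method=method,
            rng=np.random.default_rng(seed),
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = _run("BCa")
            lo, hi = res.confidence_interval
            if np.isfinite(lo) and np.isfinite(hi):
                return float(lo), float(hi), "bca"
        except Exception:
            pass
        res = _run("percentile")
        lo, hi = res.confidence_interval
    return float(lo), float(hi), "percentile"


def call_outliers(
    matrix: CohortMatrix,
    background_label: str = "control",
    q: float = DEFAULT_QUANTILE,
    conf: float = DEFAULT_CONF,
    n_boot: int = DEFAULT_N_BOOT,
    seed: int = 0,
) -> List[OutlierResult]:
    """Flag non-background samples exceeding the background quantile bound.

    For every motif in the cohort matrix the upper confidence bound of the
    background's q-quantile is estimated from background-labelled samples
    only; each remaining sample is flagged iff its score **strictly**
    exceeds that bound.  Results are sorted by (motif, sample_id).
    """
    bg_mask = (matrix.labels == background_label).to_numpy()
    n_bg = int(bg_mask.sum())
    if n_bg < MIN_BACKGROUND:
        raise ValueError(
            f"background group {background_label!r} has {n_bg} samples; "
            f"at least {MIN_BACKGROUND} are required"
        )
    if bg_mask.all():
        raise ValueError("cohort contains only background samples")
    motifs = list(matrix.scores.columns)
    seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(len(motifs))
    ]
    results: List[OutlierResult] = []
    query_ids = matrix.scores.index[~bg_mask]
    for motif, motif_seed in zip(motifs, seeds):
        background = matrix.scores.loc[bg_mask, motif].to_numpy()
        _, upper, method = quantile_ci_bca(
            background, q=q, conf=conf, n_boot=n_boot, seed=motif_seed
        )
        for sample_id in query_ids:
            score = float(matrix.scores.at[sample_id, motif])
            results.append(
                OutlierResult(
                    motif=motif,
                    sample_id=str(sample_id),
                    score=score,
                    background_n=n_bg,
                    upper_bound=upper,
                    method=method,
                    is_outlier=score > upper,
                )
            )
    results.sort(key=lambda r: (r.motif, r.sample_id))
    return results
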