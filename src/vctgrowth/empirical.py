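"""Empirical growth-rate statistics on measured nodule series.

For a nodule with n scans, every forward-in-time scan pair (i, j), i < j,
yields one growth-rate estimate k = ln(Vj/Vi)/(tj - ti) — C(n, 2) pairs in
all.  Counting how often a truly stable nodule's pairwise k lands inside
the malignancy decision band gives the empirical false-positive rate,
directly comparable to the analytic rate from the proportional-error
model.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import InsufficientDataError, ValidationError
from .growth import VolumePair, k_from_pair
from .io import NoduleSeries
from .rates import DEFAULT_WINDOW, GrowthWindow

__all__ = [
    "PairObservation",
    "forward_pairs",
    "empirical_fpr",
    "stability_filter",
    "simulated_interval_sweep",
]


@dataclass(frozen=True)
class PairObservation:
    """One forward-in-time scan pair with its growth-rate estimate.

    Scan indices are 1-based positions in the date-sorted series;
    ``positive`` is None until the pair has been classified against a
    decision window.
    """

    nodule_id: str
    scan_index_1: int
    scan_index_2: int
    pair: VolumePair
    k: float
    positive: bool | None = None


def forward_pairs(series: NoduleSeries) -> list[PairObservation]:
    """All C(n, 2) forward-in-time scan pairs of one nodule, with k filled.

    Duplicate scan dates are rejected: a zero elapsed time leaves the rate
    undefined.
    """
    if series.n_scans < 2:
        raise InsufficientDataError(
            f"nodule {series.nodule_id}: need >= 2 scans for pairs"
        )
    days = series.days
    if len(set(days.tolist())) != len(days):
        raise ValidationError(
            f"nodule {series.nodule_id}: duplicate scan dates (delta_t = 0)"
        )
    out = []
    for i, j in itertools.combinations(range(series.n_scans), 2):
        pair = VolumePair(
            v1=float(series.volumes[i]),
            v2=float(series.volumes[j]),
            delta_t=float(days[j] - days[i]),
        )
        out.append(
            PairObservation(
                nodule_id=series.nodule_id,
                scan_index_1=i + 1,
                scan_index_2=j + 1,
                pair=pair,
                k=k_from_pair(pair).k,
            )
        )
    return out


def empirical_fpr(
    cohort: Sequence[NoduleSeries], window: GrowthWindow = DEFAULT_WINDOW
) -> tuple[float, int, int]:
    """Fraction of all forward scan pairs whose k falls in the decision band.

    Returns (fraction, positives, total_pairs); total_pairs is the
    combinatorial sum of C(n_i, 2) over nodules.  Window membership is
    strict on both sides.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    positives = 0
    total = 0
    for series in cohort:
        for obs in forward_pairs(series):
            total += 1
            positives += bool(window.contains(obs.k))
    return positives / total, positives, total


def stability_filter(
    series: NoduleSeries, threshold: float = 0.25, reference: str = "mean"
) -> bool:
    """Whether a series qualifies as stable under a max-deviation rule.

    True iff every measured volume deviates from the reference volume by
    at most ``threshold`` (fractionally).  The reference is the per-nodule
    mean by default, matching the mean-centered variance analysis; "first"
    uses the first scan instead.
    """
    if series.n_scans < 2:
        raise InsufficientDataError(
            f"nodule {series.nodule_id}: need >= 2 scans"
        )
    if reference == "mean":
        ref = float(np.mean(series.volumes))
    elif reference == "first":
        ref = float(series.volumes[0])
    else:
        raise ValidationError(f"unknown reference {reference!r}")
    return bool(np.max(np.abs(series.volumes - ref)) / ref <= threshold)


def simulated_interval_sweep(
    cohort: Sequence[NoduleSeries],
    delta_ts: Sequence[float],
    window: GrowthWindow = DEFAULT_WINDOW,
) -> list[tuple[float, float]]:
    """Empirical FPR of two-scan repeat pairs re-dated to imposed intervals.

    Emulates same-day repeat-scan (\"coffee break\") designs: each series
    must hold exactly two measurements, whose volume ratio is kept while
    the elapsed time is replaced by each candidate interval.  Returns
    (delta_t, fpr) per interval.
    """
    if len(cohort) == 0:
        raise InsufficientDataError("empty cohort")
    for series in cohort:
        if series.n_scans != 2:
            raise ValidationError(
                f"nodule {series.nodule_id}: interval sweep needs exactly 2 "
                f"scans, got {series.n_scans}"
            )
    log_ratios = np.array(
        [math.log(s.volumes[1] / s.volumes[0]) for s in cohort]
    )
    out = []
    for dt in delta_ts:
        if dt <= 0:
            raise ValidationError(f"scan interval must be positive, got {dt}")
        k = log_ratios / dt
        out.append((float(dt), float(np.mean(window.contains(k)))))
    return out
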