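"""Proportional volume-measurement-error model.

Repeat scans of a truly stable nodule scatter about its mean measured
volume.  Across nodules spanning two orders of magnitude in volume, the
per-nodule standard deviation grows linearly with the mean:

    sigma_V = a * Vbar

with no intercept.  The slope ``a`` is the single reproducibility
parameter of the whole pipeline: it feeds the growth-rate standard error
``sigma_k = a*sqrt(2)/dt`` and hence the false-positive rate of any
doubling-time decision rule.

Because every nodule here contributes more than two repeat measurements,
a Bland-Altman difference analysis does not apply; the repeated-measures
route is a linear regression of the per-nodule SD on the per-nodule mean,
constrained through the origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .errors import InsufficientDataError, ValidationError
from .io import NoduleSeries

__all__ = [
    "NoduleSummary",
    "ProportionalErrorFit",
    "summarize_nodule",
    "fit_proportional_sd",
    "cv_profile",
]


@dataclass(frozen=True)
class NoduleSummary:
    """Per-nodule repeat-measurement statistics.

    mean_volume is the arithmetic mean (mm^3), sd_volume the sample SD
    (n-1 denominator), and cv = sd_volume / mean_volume.
    """

    nodule_id: str
    mean_volume: float
    sd_volume: float
    cv: float
    n_scans: int

    def __post_init__(self) -> None:
        if not self.mean_volume > 0:
            raise ValidationError("mean_volume must be positive")
        if self.sd_volume < 0:
            raise ValidationError("sd_volume must be non-negative")


@dataclass(frozen=True)
class ProportionalErrorFit:
    """Through-origin least-squares fit of sigma_V = a * Vbar.

    ``r_squared`` is centered (1 - SS_res / sum((y - ybar)^2)) so that it
    is comparable with ordinary regression R^2; the uncentered value that
    a no-intercept fit natively produces is kept in
    ``r_squared_uncentered``.  ``p_value`` is the two-sided t-test of
    slope = 0 on n - 1 degrees of freedom.
    """

    slope: float
    slope_se: float
    r_squared: float
    r_squared_uncentered: float
    p_value: float
    n_nodules: int


def summarize_nodule(series: NoduleSeries) -> NoduleSummary:
    """Mean, sample SD and CV of one nodule's repeat volume measurements."""
    if series.n_scans < 2:
        raise InsufficientDataError(
            f"nodule {series.nodule_id}: need >= 2 scans, got {series.n_scans}"
        )
    mean = float(np.mean(series.volumes))
    sd = float(np.std(series.volumes, ddof=1))
    return NoduleSummary(
        nodule_id=series.nodule_id,
        mean_volume=mean,
        sd_volume=sd,
        cv=sd / mean,
        n_scans=series.n_scans,
    )


def fit_proportional_sd(summaries: Sequence[NoduleSummary]) -> ProportionalErrorFit:
    """Fit the proportional-error slope a of sigma_V = a * Vbar.

    Ordinary least squares with the intercept fixed at zero, per-nodule
    SD regressed on per-nodule mean volume.
    """
    if len(summaries) < 2:
        raise InsufficientDataError(
            f"need >= 2 nodule summaries for a slope, got {len(summaries)}"
        )
    x = np.array([s.mean_volume for s in summaries])
    y = np.array([s.sd_volume for s in summaries])

    model = sm.OLS(y, x[:, None]).fit()
    slope = float(model.params[0])
    resid = y - slope * x
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2_centered = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return ProportionalErrorFit(
        slope=slope,
        slope_se=float(model.bse[0]),
        r_squared=r2_centered,
        r_squared_uncentered=float(model.rsquared),
        p_value=float(model.pvalues[0]),
        n_nodules=len(summaries),
    )


def cv_profile(
    summaries: Sequence[NoduleSummary],
    volume_threshold: float = 100.0,
    cv_limit: float = 0.15,
) -> float:
    """Fraction of nodules above a volume threshold whose CV is below a limit.

    Used to check claims like "above 100 mm^3 the CV stays under 0.15".
    Returns the proportion among nodules with mean_volume > volume_threshold;
    if none exceed the threshold the fraction over the whole list is returned.
    """
    if not summaries:
        raise InsufficientDataError("empty summary list")
    above = [s for s in summaries if s.mean_volume > volume_threshold]
    pool = above if above else list(summaries)
    return sum(1 for s in pool if s.cv < cv_limit) / len(pool)
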