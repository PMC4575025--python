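"""Exponential nodule growth kinetics and error propagation.

A nodule is assumed to grow (or stay stable) following

    V(t) = V(0) * exp(k * t)

with the growth-rate constant ``k`` in day^-1 and time in days.  The
doubling time relates to the rate constant by ``DT = ln 2 / k``.  Stable
nodules have k = 0; their apparent growth between two scans is pure
measurement noise.

When each volume measurement carries a standard deviation proportional to
the volume itself (sigma_V = a * V), first-order error propagation of
``k = ln(V2/V1) / dt`` gives a growth-rate standard error

    sigma_k = a * sqrt(2) / dt

which is independent of the nodule volume — the property that makes a
single optimal follow-up interval possible for nodules of any size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "GrowthEstimate",
    "VolumePair",
    "volume_at",
    "k_from_pair",
    "k_from_dt",
    "dt_from_k",
    "propagate_sigma_k",
    "sigma_k_proportional",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class VolumePair:
    """Two dated volume measurements of one nodule.

    Parameters
    ----------
    v1, v2 : float
        Volumes (mm^3) at the first and second scan; both strictly positive.
    delta_t : float
        Elapsed time between the scans in days; strictly positive.
    """

    v1: float
    v2: float
    delta_t: float

    def __post_init__(self) -> None:
        if not self.v1 > 0 or not self.v2 > 0:
            raise ValidationError(
                f"volumes must be positive, got v1={self.v1}, v2={self.v2}"
            )
        if not self.delta_t > 0:
            raise ValidationError(
                f"delta_t must be positive, got {self.delta_t}"
            )


@dataclass(frozen=True)
class GrowthEstimate:
    """A growth-rate constant with (optionally) its standard error.

    ``doubling_time`` is ``ln2 / k`` in days; for a stable nodule (k = 0)
    it is reported as ``math.inf`` rather than overflowing.  A negative k
    (shrinkage) gives a negative doubling time, i.e. a halving time.
    """

    k: float
    sigma_k: float | None = None

    def __post_init__(self) -> None:
        if self.sigma_k is not None and self.sigma_k < 0:
            raise ValidationError(f"sigma_k must be >= 0, got {self.sigma_k}")

    @property
    def doubling_time(self) -> float:
        if self.k == 0.0:
            return math.inf
        return LN2 / self.k


def volume_at(v0: float, k: float, t: float) -> float:
    """Volume after ``t`` days of exponential growth at rate ``k``.

    Returns ``v0 * exp(k * t)``; always strictly positive.
    """
    if not v0 > 0:
        raise ValidationError(f"initial volume must be positive, got {v0}")
    return v0 * math.exp(k * t)


def k_from_pair(pair: VolumePair) -> GrowthEstimate:
    """Growth-rate constant from a scan pair: ``k = ln(v2/v1) / delta_t``.

    Antisymmetric under swapping v1 and v2.  ``sigma_k`` is left unset;
    use :func:`propagate_sigma_k` or :func:`sigma_k_proportional` for it.
    """
    k = math.log(pair.v2 / pair.v1) / pair.delta_t
    return GrowthEstimate(k=k)


def k_from_dt(dt: float) -> float:
    """Rate constant (day^-1) for a doubling time of ``dt`` days."""
    if not dt > 0:
        raise ValidationError(f"doubling time must be positive, got {dt}")
    return LN2 / dt


def dt_from_k(k: float) -> float:
    """Doubling time (days) for a rate constant ``k`` (day^-1)."""
    if not k > 0:
        raise ValidationError(f"rate constant must be positive, got {k}")
    return LN2 / k


def propagate_sigma_k(
    v1: float, sigma_v1: float, v2: float, sigma_v2: float, delta_t: float
) -> float:
    """Standard error of k from the volume measurement errors.

    First-order propagation through ``k = ln(v2/v1)/delta_t``:

        sigma_k = sqrt[(sigma_v1 / (delta_t*v1))^2 + (sigma_v2 / (delta_t*v2))^2]

    With proportional errors sigma_vi = a*vi this reduces to
    ``a*sqrt(2)/delta_t`` (see :func:`sigma_k_proportional`).
    """
    if not (v1 > 0 and v2 > 0):
        raise ValidationError("volumes must be positive")
    if sigma_v1 < 0 or sigma_v2 < 0:
        raise ValidationError("volume SDs must be non-negative")
    if not delta_t > 0:
        raise ValidationError(f"delta_t must be positive, got {delta_t}")
    return math.hypot(sigma_v1 / (delta_t * v1), sigma_v2 / (delta_t * v2))


def sigma_k_proportional(a: float, delta_t: float) -> float:
    """Growth-rate standard error under the proportional-error model.

    ``sigma_k = a * sqrt(2) / delta_t`` — notably independent of the
    nodule volume, hence no volume argument.
    """
    if a < 0:
        raise ValidationError(f"error slope must be >= 0, got {a}")
    if not delta_t > 0:
        raise ValidationError(f"delta_t must be positive, got {delta_t}")
    return a * math.sqrt(2.0) / delta_t
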