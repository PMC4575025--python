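"""Synthetic nodule cohorts with proportional measurement noise.

Generates longitudinal volume series with the statistical structure the
analysis pipeline assumes, so every stage can be exercised and calibrated
without patient data.  The default configuration mirrors the study
conditions the pipeline was built around: 89 stable non-calcified nodules
of 3-1300 mm^3 with 3-8 scans each (frequencies 44:26:9:6:1:3), volume
measurement noise with SD proportional to the true volume (slope 0.057;
0.052 for the calcified arm), and a malignant arm whose growth-rate
constant is drawn from lognormal(ln 0.015, 0.83).

Sample-SD calibration
---------------------
The proportional-error slope ``a`` is an *observable*: it is estimated by
regressing per-nodule sample SDs (n-1 denominator, n = 3-8 scans) on mean
volumes.  The sample SD of a small Gaussian sample underestimates the true
SD by the classical c4(n) factor (E[s] = c4(n) * sigma, c4(3) = 0.886).
By default the generator therefore draws noise with per-measurement SD
``a * V / c4(n)`` so that the *expected sample SD* of an n-scan series is
exactly ``a * V`` and the fitted slope is centred on ``a``.  Set
``calibrate_sample_sd=False`` to make the true per-draw SD equal ``a * V``
instead — the right mode when comparing Monte-Carlo classification rates
with analytic formulas whose premise is sigma_V = a*V.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
from scipy.special import gammaln

from .errors import ValidationError
from .io import NoduleSeries

__all__ = [
    "CohortConfig",
    "SCAN_COUNT_FREQUENCIES",
    "c4",
    "simulate_measurement",
    "simulate_cohort",
    "simulate_calcified_arm",
]

# scan-count mix of the 89-nodule stable arm: 44 nodules with 3 scans, etc.
SCAN_COUNT_FREQUENCIES: dict[int, int] = {3: 44, 4: 26, 5: 9, 6: 6, 7: 1, 8: 3}

EPOCH = date(2010, 1, 1)  # arbitrary calendar anchor; only day differences matter


def c4(n: int) -> float:
    """Small-sample bias factor of the Gaussian sample SD: E[s] = c4(n)*sigma."""
    if n < 2:
        raise ValidationError(f"c4 defined for n >= 2, got {n}")
    return math.exp(
        0.5 * math.log(2.0 / (n - 1)) + gammaln(n / 2.0) - gammaln((n - 1) / 2.0)
    )


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for one synthetic cohort.

    scans_per_nodule maps scan count to relative frequency; gaps between
    consecutive scans are uniform over ``inter_scan_gap`` (days).  For the
    malignant arm, each nodule's k is lognormal(mu_log, sigma_log) and the
    true volume evolves exponentially between scans.
    """

    n_nodules: int = 89
    scans_per_nodule: dict[int, float] = field(
        default_factory=lambda: dict(SCAN_COUNT_FREQUENCIES)
    )
    true_volume_range: tuple[float, float] = (3.0, 1300.0)
    inter_scan_gap: tuple[float, float] = (60.0, 400.0)
    error_slope: float = 0.057
    growth_model: str = "stable"  # "stable" | "malignant"
    mu_log: float = math.log(0.015)
    sigma_log: float = 0.83
    calcified: bool = False
    noise: str = "gaussian"  # "gaussian" | "lognormal"
    calibrate_sample_sd: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodules < 1:
            raise ValidationError(f"n_nodules must be >= 1, got {self.n_nodules}")
        lo, hi = self.true_volume_range
        if not 0 < lo < hi:
            raise ValidationError(f"bad volume range ({lo}, {hi})")
        glo, ghi = self.inter_scan_gap
        if not 0 < glo <= ghi:
            raise ValidationError(f"bad inter-scan gap ({glo}, {ghi})")
        if self.error_slope < 0:
            raise ValidationError(f"error slope must be >= 0, got {self.error_slope}")
        if self.growth_model not in {"stable", "malignant"}:
            raise ValidationError(f"unknown growth model {self.growth_model!r}")
        if self.noise not in {"gaussian", "lognormal"}:
            raise ValidationError(f"unknown noise model {self.noise!r}")
        if not self.scans_per_nodule or any(
            (n < 2 or w < 0) for n, w in self.scans_per_nodule.items()
        ) or sum(self.scans_per_nodule.values()) <= 0:
            raise ValidationError("scans_per_nodule must be counts >= 2 with positive weight")


def simulate_measurement(
    true_volume: float, a: float, rng: np.random.Generator
) -> float:
    """One noisy volume measurement with SD = a * true_volume.

    Additive zero-mean Gaussian noise; non-positive draws are resampled
    (not clipped) so the mean stays unbiased.
    """
    if not true_volume > 0:
        raise ValidationError(f"true volume must be positive, got {true_volume}")
    if a < 0:
        raise ValidationError(f"error slope must be >= 0, got {a}")
    if a == 0:
        return true_volume
    while True:
        v = true_volume + rng.normal(0.0, a * true_volume)
        if v > 0:
            return v


def _noisy(true_vols: np.ndarray, sd_slope: float, noise: str, rng) -> np.ndarray:
    if sd_slope == 0:
        return true_vols.copy()
    if noise == "gaussian":
        out = true_vols + rng.normal(0.0, sd_slope * true_vols)
        bad = out <= 0
        while np.any(bad):
            out[bad] = true_vols[bad] + rng.normal(0.0, sd_slope * true_vols[bad])
            bad = out <= 0
        return out
    # multiplicative lognormal with matched CV, for sensitivity analysis
    s = math.sqrt(math.log1p(sd_slope**2))
    return true_vols * rng.lognormal(-0.5 * s * s, s, size=true_vols.shape)


def simulate_cohort(config: CohortConfig) -> list[NoduleSeries]:
    """Generate a reproducible cohort of measured nodule series.

    Stable nodules have constant true volume; malignant nodules evolve it
    exponentially with a per-nodule k drawn from the configured lognormal.
    Scan dates start at an arbitrary calendar anchor with independently
    drawn gaps.  Identical config (seed included) gives an identical
    cohort.
    """
    rng = np.random.default_rng(config.seed)
    counts = sorted(config.scans_per_nodule)
    weights = np.array([config.scans_per_nodule[n] for n in counts], dtype=float)
    weights /= weights.sum()

    series = []
    prefix = "cal" if config.calcified else "nod"
    for i in range(config.n_nodules):
        n_scans = int(rng.choice(counts, p=weights))
        v0 = rng.uniform(*config.true_volume_range)
        gaps = rng.uniform(*config.inter_scan_gap, size=n_scans - 1)
        days = np.concatenate([[0.0], np.cumsum(np.round(gaps))])
        if config.growth_model == "malignant":
            k = rng.lognormal(config.mu_log, config.sigma_log)
            true_vols = v0 * np.exp(k * days)
        else:
            true_vols = np.full(n_scans, v0)
        sd_slope = config.error_slope
        if config.calibrate_sample_sd:
            sd_slope /= c4(n_scans)
        measured = _noisy(true_vols, sd_slope, config.noise, rng)
        series.append(
            NoduleSeries(
                nodule_id=f"{prefix}{i:04d}",
                patient_id=f"pt{i:04d}",
                dates=[EPOCH + timedelta(days=int(d)) for d in days],
                volumes=measured,
                calcified=config.calcified,
                true_volumes=true_vols,
            )
        )
    return series


def simulate_calcified_arm(config: CohortConfig | None = None) -> list[NoduleSeries]:
    """Calcified-nodule validation arm: by default 49 stable nodules with
    error slope 0.052.  A supplied config is used as-is apart from the
    calcified flag."""
    if config is None:
        config = CohortConfig(n_nodules=49, error_slope=0.052)
    config = dataclasses.replace(config, calcified=True)
    return simulate_cohort(config)
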