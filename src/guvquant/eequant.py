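"""Encapsulation-efficiency quantification and batch statistics.

Two measurement channels see the same vesicles: wide-field microscopy
yields an arbitrary-unit total fluorescence ``I`` per GUV, and the
single-molecule microarray yields an absolute molecule count ``N``.  Both
scale with vesicle volume as power laws, ``I = a_mu V^k`` and
``N = a_sm V^k`` with a common exponent ``k``, so their quotient
``a_sm / a_mu`` is a volume-independent factor that converts microscopy
intensities to absolute molecule numbers.

Per vesicle, the encapsulation efficiency is

    EE (%) = 100 * N_measured / (C_seed * V)

where ``C_seed`` is the seed-solution concentration (molecules/pL) and
``V`` the vesicle volume (pL).  Values above 100% are retained and flagged
(super-concentrated vesicles are real observations, not artefacts).
Batch summaries use Tukey box-whisker conventions: whiskers extend to the
most extreme values within 1.5 IQR of the quartiles, points beyond are
outliers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, InsufficientDataError

__all__ = [
    "PowerLawFit",
    "EERecord",
    "BatchStats",
    "fit_shared_powerlaw",
    "calibrate_microscopy",
    "expected_copies",
    "ee_percent",
    "batch_stats",
]


@dataclass(frozen=True)
class PowerLawFit:
    """Joint power-law fit with a shared exponent.

    ``scale_ratio = a_sm / a_mu`` converts arbitrary-unit intensities to
    molecules.  ``k_micro``/``k_sm`` are the independently fitted slopes,
    kept as a diagnostic of the shared-exponent assumption.
    """

    a_mu: float
    a_sm: float
    k: float
    scale_ratio: float
    fit_rms: float
    k_micro: float = float("nan")
    k_sm: float = float("nan")

    def __post_init__(self):
        if self.a_mu <= 0 or self.a_sm <= 0:
            raise ConfigurationError("power-law prefactors must be positive")


@dataclass(frozen=True)
class EERecord:
    guv_id: int
    volume_pl: float
    measured_copies: float
    expected_copies: float
    ee: float  # percent
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class BatchStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    whisker_low: float
    whisker_high: float
    outliers: tuple[float, ...]
    span_orders: float


def _as_log10_xy(pairs, name):
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ConfigurationError(f"{name} must be a sequence of (volume, value) pairs")
    if arr.shape[0] < 3:
        raise InsufficientDataError(f"{name} needs at least 3 points")
    if np.any(arr <= 0):
        raise ConfigurationError(f"{name} volumes and values must be positive")
    return np.log10(arr[:, 0]), np.log10(arr[:, 1])


def fit_shared_powerlaw(micro, sm) -> PowerLawFit:
    """Fit ``I = a_mu V^k`` and ``N = a_sm V^k`` with one shared ``k``.

    Implemented as a single linear regression in log10-log10 space with a
    common slope and separate intercepts (exact for noiseless power-law
    data).  The independent slopes of each dataset are reported alongside
    as a diagnostic.
    """
    lv_mu, ly_mu = _as_log10_xy(micro, "micro")
    lv_sm, ly_sm = _as_log10_xy(sm, "sm")

    n_mu, n_sm = len(lv_mu), len(lv_sm)
    design = np.zeros((n_mu + n_sm, 3))
    design[:n_mu, 0] = 1.0
    design[n_mu:, 1] = 1.0
    design[:, 2] = np.concatenate([lv_mu, lv_sm])
    target = np.concatenate([ly_mu, ly_sm])
    coef, *_ = np.linalg.lstsq(design, target, rcond=None)
    resid = target - design @ coef
    a_mu = 10.0 ** coef[0]
    a_sm = 10.0 ** coef[1]
    k = float(coef[2])

    def _slope(lx, ly):
        if np.ptp(lx) == 0:
            return float("nan")
        return float(np.polyfit(lx, ly, 1)[0])

    return PowerLawFit(
        a_mu=float(a_mu),
        a_sm=float(a_sm),
        k=k,
        scale_ratio=float(a_sm / a_mu),
        fit_rms=float(np.sqrt(np.mean(resid**2))),
        k_micro=_slope(lv_mu, ly_mu),
        k_sm=_slope(lv_sm, ly_sm),
    )


def calibrate_microscopy(intensity, fit: PowerLawFit):
    """Convert arbitrary-unit intensities to molecules via ``scale_ratio``.

    Because both power laws share the exponent ``k``, the conversion is a
    plain volume-independent multiplication.
    """
    arr = np.asarray(intensity, dtype=float)
    if np.any(arr < 0):
        raise ConfigurationError("intensity must be >= 0")
    out = fit.scale_ratio * arr
    return out if out.ndim else float(out)


def expected_copies(volume_pl: float, seed_conc: float) -> float:
    """Expected encapsulated copies: seed concentration times volume."""
    if volume_pl <= 0:
        raise ConfigurationError("volume must be > 0")
    if seed_conc < 0:
        raise ConfigurationError("seed_conc must be >= 0")
    return float(seed_conc * volume_pl)


def ee_percent(measured: float, expected: float) -> float:
    """Encapsulation efficiency in percent; > 100% is allowed (and real)."""
    if expected <= 0:
        raise ConfigurationError("expected copies must be > 0")
    if measured < 0:
        raise ConfigurationError("measured copies must be >= 0")
    return 100.0 * measured / expected


def batch_stats(ees) -> BatchStats:
    """Summary statistics of a batch of per-GUV EE values (percent).

    Quartiles use linear interpolation between order statistics; the SD is
    the sample SD; whiskers and outliers follow the Tukey convention
    (fences at the quartiles plus/minus 1.5 IQR).  ``span_orders`` is
    ``log10(max / min)``.  Censored (below-LOD) records must be excluded
    by the caller and reported separately.
    """
    arr = np.asarray(list(ees), dtype=float)
    if arr.size == 0:
        raise InsufficientDataError("batch is empty")
    if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
        raise ConfigurationError("EE values must be positive and finite")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    iqr = q3 - q1
    hi_fence = q3 + 1.5 * iqr
    lo_fence = q1 - 1.5 * iqr
    inside = arr[(arr >= lo_fence) & (arr <= hi_fence)]
    outliers = tuple(float(v) for v in np.sort(arr[(arr < lo_fence) | (arr > hi_fence)]))
    return BatchStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        whisker_low=float(inside.min()),
        whisker_high=float(inside.max()),
        outliers=outliers,
        span_orders=float(math.log10(arr.max() / arr.min())),
    )
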