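"""Five-parameter logistic (5PL) calibration of single-molecule counts.

The standard curve relates the number of molecules per chamber ``x`` to
the number of single molecules counted on the spot:

    y(x) = n_bkd + (n_sat - n_bkd) / (1 + (c / x)^m)^A

with background asymptote ``n_bkd``, saturation asymptote ``n_sat``, slope
``m``, inflection ``c`` and asymmetry ``A`` (``A = 1`` reduces to the
symmetric 4PL).  The curve is fitted to standards in log-log space and
inverted in closed form to convert observed counts into absolute molecules
per chamber.  Counts at or below the background asymptote are censored at
the limit of detection rather than forced to zero; counts at or above
saturation raise an error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .errors import (
    ConfigurationError,
    FitError,
    InsufficientDataError,
    SaturatedSignalError,
)
from .guvforge import CalStandard

__all__ = [
    "FivePLParams",
    "CalibrationCurve",
    "Inversion",
    "fivepl_eval",
    "fit_fivepl",
    "invert_fivepl",
]


@dataclass(frozen=True)
class FivePLParams:
    n_bkd: float
    n_sat: float
    m: float
    c: float
    a: float

    def __post_init__(self):
        if not (self.n_sat > self.n_bkd >= 0):
            raise ConfigurationError("require n_sat > n_bkd >= 0")
        if self.m <= 0 or self.c <= 0 or self.a <= 0:
            raise ConfigurationError("m, c and A must be strictly positive")


@dataclass(frozen=True)
class CalibrationCurve:
    """A fitted standard curve with its validity range and diagnostics.

    ``valid_range`` is the span of the fitted standards; inversions outside
    it are flagged as extrapolated, which should be avoided to minimise
    uncertainty.  ``fit_rms`` is the RMS residual in log10 counts.
    """

    params: FivePLParams
    valid_range: tuple[float, float]
    fit_rms: float
    n_points: int

    def to_text(self) -> str:
        p = self.params
        lines = [
            f"n_bkd: {p.n_bkd!r}",
            f"n_sat: {p.n_sat!r}",
            f"m: {p.m!r}",
            f"c: {p.c!r}",
            f"A: {p.a!r}",
            f"valid_min: {self.valid_range[0]!r}",
            f"valid_max: {self.valid_range[1]!r}",
            f"fit_rms: {self.fit_rms!r}",
            f"n_points: {self.n_points}",
        ]
        return "\n".join(lines) + "\n"

    @classmethod
    def from_text(cls, text: str) -> "CalibrationCurve":
        kv = {}
        for line in text.strip().splitlines():
            key, _, val = line.partition(":")
            kv[key.strip()] = float(val)
        return cls(
            params=FivePLParams(kv["n_bkd"], kv["n_sat"], kv["m"], kv["c"], kv["A"]),
            valid_range=(kv["valid_min"], kv["valid_max"]),
            fit_rms=kv["fit_rms"],
            n_points=int(kv["n_points"]),
        )


def fivepl_eval(x, p: FivePLParams):
    """Expected count for ``x`` molecules per chamber; strictly increasing.

    ``y(0) = n_bkd`` (the limit) and ``y -> n_sat`` as ``x -> inf``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ConfigurationError("x must be >= 0")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x_arr > 0, p.c / np.maximum(x_arr, 1e-300), np.inf)
        y = p.n_bkd + (p.n_sat - p.n_bkd) / (1.0 + ratio**p.m) ** p.a
    y = np.where(x_arr > 0, y, p.n_bkd)
    return y if y.ndim else float(y)


@dataclass(frozen=True)
class Inversion:
    """Result of inverting a count through the calibration curve.

    ``molecules`` is NaN when the count is censored at the limit of
    detection (at or below the background asymptote).
    """

    molecules: float
    censored: bool = False
    extrapolated: bool = False

    def __float__(self):
        return self.molecules


def invert_fivepl(y: float, curve: CalibrationCurve) -> Inversion:
    """Closed-form inverse of the 5PL; flags censoring and extrapolation."""
    p = curve.params
    if y >= p.n_sat:
        raise SaturatedSignalError(
            f"count {y} at or above the saturation asymptote {p.n_sat}"
        )
    if y <= p.n_bkd:
        return Inversion(molecules=float("nan"), censored=True)
    x = p.c * (((p.n_sat - p.n_bkd) / (y - p.n_bkd)) ** (1.0 / p.a) - 1.0) ** (-1.0 / p.m)
    lo, hi = curve.valid_range
    return Inversion(molecules=float(x), extrapolated=not (lo <= x <= hi))


def _gather(standards: list[CalStandard]):
    xs, ys = [], []
    for s in standards:
        if s.observed_count is None:
            raise InsufficientDataError("standard has no observed count")
        xs.append(s.molecules_per_chamber)
        ys.append(s.observed_count)
    return np.asarray(xs, float), np.asarray(ys, float)


def fit_fivepl(standards: list[CalStandard]) -> CalibrationCurve:
    """Fit the 5PL to standards by least squares in log-log space.

    Requires at least 6 distinct positive levels spanning >= 3 orders of
    magnitude.  Initialisation is asymptote-anchored: ``n_bkd`` from the
    smallest counts, ``n_sat`` from the largest, ``c`` at the level halfway
    through the log range, ``m = A = 1``; the fit is therefore reproducible
    for identical inputs.
    """
    x, y = _gather(standards)
    pos = x > 0
    x_pos, y_pos = x[pos], y[pos]
    levels = np.unique(x_pos)
    if len(levels) < 6:
        raise InsufficientDataError("need >= 6 distinct positive standard levels")
    if np.log10(levels.max() / levels.min()) < 3.0:
        raise InsufficientDataError("standard levels must span >= 3 orders of magnitude")
    if np.any(y_pos <= 0):
        raise InsufficientDataError("observed counts must be positive for a log-space fit")
    if y_pos.max() / y_pos.min() < 1.5:
        raise FitError(
            "standards have no dynamic range (counts nearly identical); "
            "degenerate curve cannot be fitted",
            last_params=None,
            residual=float(np.std(np.log10(y_pos))),
        )

    y_min, y_max = y_pos.min(), y_pos.max()
    c0 = math.sqrt(levels.min() * levels.max())
    # theta = (log10 n_bkd, log10 span, log10 m, log10 c, log10 A)
    theta0 = np.array(
        [math.log10(max(y_min, 1e-6)), math.log10(y_max - 0.5 * y_min), 0.0, math.log10(c0), 0.0]
    )
    log_y = np.log10(y_pos)

    def unpack(theta):
        n_bkd = float(10.0 ** theta[0])
        n_sat = float(n_bkd + 10.0 ** theta[1])
        return FivePLParams(
            n_bkd, n_sat, float(10.0 ** theta[2]), float(10.0 ** theta[3]), float(10.0 ** theta[4])
        )

    def resid(theta):
        # raw evaluation: intermediate iterates may momentarily violate the
        # parameter invariants, so do not route through FivePLParams here
        theta = np.clip(theta, -300.0, 300.0)
        n_bkd = 10.0 ** theta[0]
        n_sat = n_bkd + 10.0 ** theta[1]
        m, c, a = 10.0 ** theta[2], 10.0 ** theta[3], 10.0 ** theta[4]
        with np.errstate(divide="ignore", over="ignore"):
            y = n_bkd + (n_sat - n_bkd) / (1.0 + (c / x_pos) ** m) ** a
        return np.log10(np.maximum(y, 1e-300)) - log_y

    res = optimize.least_squares(resid, theta0, method="lm", max_nfev=5000)
    if not res.success or not np.all(np.isfinite(res.x)):
        raise FitError(
            "5PL fit did not converge",
            last_params=unpack(res.x) if np.all(np.isfinite(res.x)) else None,
            residual=float(np.sqrt(np.mean(res.fun**2))),
        )
    params = unpack(res.x)
    return CalibrationCurve(
        params=params,
        valid_range=(float(levels.min()), float(levels.max())),
        fit_rms=float(np.sqrt(np.mean(res.fun**2))),
        n_points=int(len(x_pos)),
    )
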