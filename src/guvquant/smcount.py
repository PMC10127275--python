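"""Single-molecule counting on microarray-spot TIRF frames.

The counting chain is: field-flatten, subtract the slowly varying
background, detect local maxima above a robust noise threshold, refine
each candidate by least-squares fitting of an isotropic 2D Gaussian, and
keep fits passing size and intensity thresholds.  When the spot is too
crowded for individual molecules to be resolved, the count falls back to
dividing the total background-subtracted spot intensity by the average
(median) integrated single-molecule intensity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage, optimize

from .errors import ConfigurationError, DataError, DenseCountError
from .regions import SpotRegion

__all__ = [
    "DetectParams",
    "DetectedMolecule",
    "SpotCount",
    "flatten_field",
    "subtract_background",
    "detect_and_fit",
    "count_spot",
    "integrated_intensity",
    "robust_noise_sd",
]


@dataclass(frozen=True)
class DetectParams:
    """Detection and fit-acceptance thresholds.

    ``local_max_threshold`` is expressed in multiples of the robust
    background SD; ``min_sigma``/``max_sigma`` bound the fitted PSF width
    (defaults are 0.5x and 2.5x a nominal 1.3 px PSF); candidates whose
    fitted amplitude falls below ``min_amplitude`` are rejected.  The
    resolved/dense decision is made on detection occupancy: each detection
    is assigned a footprint of radius ``2 * nominal_sigma`` and the spot is
    declared dense when footprints cover more than
    ``dense_occupancy_threshold`` of the spot area.
    """

    fit_window: int = 21
    min_sigma: float = 0.65
    max_sigma: float = 3.25
    min_amplitude: float = 250.0
    local_max_threshold: float = 5.0
    dense_occupancy_threshold: float = 0.10
    max_fits: int = 4000

    def __post_init__(self):
        if not (0 < self.min_sigma < self.max_sigma):
            raise ConfigurationError("require 0 < min_sigma < max_sigma")
        if self.fit_window % 2 == 0:
            raise ConfigurationError("fit_window must be odd")
        if self.fit_window < 2 * math.ceil(3 * self.max_sigma) + 1:
            # a window smaller than the widest acceptable PSF cannot constrain it
            raise ConfigurationError("fit_window must be >= 2*ceil(3*max_sigma)+1")
        if not (0 < self.dense_occupancy_threshold < 1):
            raise ConfigurationError("dense_occupancy_threshold must lie in (0, 1)")

    @property
    def nominal_sigma(self) -> float:
        return math.sqrt(self.min_sigma * self.max_sigma)


@dataclass(frozen=True)
class DetectedMolecule:
    """A fitted single-molecule localisation (sub-pixel)."""

    x: float
    y: float
    amplitude: float
    sigma: float
    local_background: float
    fit_residual: float


@dataclass(frozen=True)
class SpotCount:
    """Molecule count for one microarray spot."""

    n_molecules: int
    mode: str  # "resolved" | "dense"
    mean_sm_intensity: float
    total_spot_intensity: float


def integrated_intensity(mol: DetectedMolecule) -> float:
    """Integrated counts of a fitted molecule, ``amplitude * 2 pi sigma^2``."""
    return float(mol.amplitude * 2.0 * np.pi * mol.sigma**2)


def flatten_field(image: np.ndarray, illumination_profile: np.ndarray) -> np.ndarray:
    """Divide out the illumination profile, normalised to unit mean.

    A constant profile (of any scale) leaves the image unchanged.
    """
    image = np.asarray(image, dtype=float)
    profile = np.asarray(illumination_profile, dtype=float)
    if profile.shape != image.shape:
        raise ConfigurationError("illumination profile shape must match the image")
    if np.any(profile <= 0):
        raise ConfigurationError("illumination profile must be strictly positive")
    return image / (profile / profile.mean())


def subtract_background(image: np.ndarray, radius: int) -> np.ndarray:
    """Remove large-scale background by grayscale opening at the given radius.

    The background estimate is a morphological opening (minimum then maximum
    filter with a ``2*radius+1`` square window) lightly smoothed; structures
    narrower than the window — such as diffraction-limited molecules — are
    preserved while slowly varying background is removed.  The result is
    clipped at zero.  ``radius`` should exceed ~3x the PSF width and, when a
    bright extended spot is present, the spot radius.
    """
    if radius < 1:
        raise ConfigurationError("radius must be >= 1")
    image = np.asarray(image, dtype=float)
    size = 2 * int(radius) + 1
    bg = ndimage.maximum_filter(ndimage.minimum_filter(image, size=size), size=size)
    bg = ndimage.gaussian_filter(bg, sigma=max(1.0, radius / 4.0))
    return np.clip(image - bg, 0.0, None)


def robust_noise_sd(image: np.ndarray) -> float:
    """MAD-based robust estimate of the pixel noise SD."""
    med = np.median(image)
    return float(1.4826 * np.median(np.abs(image - med)))


def _gauss_model(params, xx, yy):
    a, x0, y0, sig, b = params
    return a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * sig**2)) + b


def _fit_peak(image, xi, yi, params: DetectParams, others=None):
    half = params.fit_window // 2
    h, w = image.shape
    x_lo, x_hi = max(0, xi - half), min(w, xi + half + 1)
    y_lo, y_hi = max(0, yi - half), min(h, yi + half + 1)
    win = image[y_lo:y_hi, x_lo:x_hi]
    yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi].astype(float)
    # a candidate's fit only sees pixels it owns: anything closer to another
    # candidate is masked out, so overlapping neighbours cannot drag the fit
    # to a shared midpoint
    own = np.ones(win.shape, dtype=bool)
    if others is not None and len(others):
        d_own = (xx - xi) ** 2 + (yy - yi) ** 2
        for ox, oy in others:
            if (ox - xi) ** 2 + (oy - yi) ** 2 < (2.0 * half) ** 2:
                own &= d_own <= (xx - ox) ** 2 + (yy - oy) ** 2
    xf, yf, wf = xx[own], yy[own], win[own]
    b0 = float(np.median(wf))
    a0 = max(float(image[yi, xi]) - b0, 1.0)
    p0 = [a0, float(xi), float(yi), params.nominal_sigma, b0]
    lo = [0.0, xi - 1.5, yi - 1.5, 0.3, -np.inf]
    hi = [np.inf, xi + 1.5, yi + 1.5, 2.0 * params.max_sigma, np.inf]

    def jac(p):
        a, x0, y0, sig, b = p
        dx, dy = xf - x0, yf - y0
        q = np.exp(-(dx**2 + dy**2) / (2.0 * sig**2))
        return np.column_stack(
            [q, a * q * dx / sig**2, a * q * dy / sig**2,
             a * q * (dx**2 + dy**2) / sig**3, np.ones_like(q)]
        )

    try:
        res = optimize.least_squares(
            lambda p: _gauss_model(p, xf, yf) - wf,
            p0,
            jac=jac,
            bounds=(lo, hi),
            method="trf",
            max_nfev=200,
        )
    except Exception:
        return None
    a, x0, y0, sig, b = res.x
    rms = math.sqrt(np.mean(res.fun**2))
    return DetectedMolecule(
        x=float(x0),
        y=float(y0),
        amplitude=float(a),
        sigma=float(sig),
        local_background=float(b),
        fit_residual=float(rms / max(a, 1e-12)),
    )


def _local_maxima(image, threshold, min_distance=1):
    size = 2 * min_distance + 1
    maxed = ndimage.maximum_filter(image, size=size, mode="nearest")
    mask = (image >= maxed) & (image > threshold)
    ys, xs = np.nonzero(mask)
    return xs, ys


def detect_and_fit(image: np.ndarray, params: DetectParams) -> list[DetectedMolecule]:
    """Detect and fit single molecules on a background-subtracted frame.

    Local maxima above ``local_max_threshold`` robust noise SDs are fitted
    with an isotropic 2D Gaussian in a ``fit_window`` square; fits failing
    the sigma or amplitude thresholds are discarded; duplicate detections
    within 1 px are merged, keeping the lower-residual fit.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise DataError("image contains non-finite pixels")
    noise = robust_noise_sd(image)
    thr = np.median(image) + params.local_max_threshold * max(noise, 1e-12)
    xs, ys = _local_maxima(image, thr)
    if len(xs) > params.max_fits:
        # keep the brightest candidates; callers hitting this limit are in
        # the dense regime and should be using count_spot
        order = np.argsort(image[ys, xs])[::-1][: params.max_fits]
        xs, ys = xs[order], ys[order]
    # suppress candidates within 2 px of a stronger one: below the resolving
    # limit of the PSF a secondary noise shoulder is the same emitter
    order = np.argsort(image[ys, xs])[::-1]
    keep_x, keep_y = [], []
    for idx in order:
        if any((xs[idx] - kx) ** 2 + (ys[idx] - ky) ** 2 < 4.0 for kx, ky in zip(keep_x, keep_y)):
            continue
        keep_x.append(int(xs[idx]))
        keep_y.append(int(ys[idx]))
    xs, ys = np.array(keep_x, dtype=int), np.array(keep_y, dtype=int)

    candidates = np.column_stack([xs, ys]).astype(float)
    fits = []
    for j, (xi, yi) in enumerate(zip(xs, ys)):
        others = np.delete(candidates, j, axis=0)
        mol = _fit_peak(image, int(xi), int(yi), params, others=others)
        if mol is None:
            continue
        if not (params.min_sigma <= mol.sigma <= params.max_sigma):
            continue
        if mol.amplitude < params.min_amplitude:
            continue
        fits.append(mol)

    # merge duplicates closer than the ~2 px resolving limit of the PSF,
    # keeping the lower-residual fit
    fits.sort(key=lambda m: m.fit_residual)
    kept: list[DetectedMolecule] = []
    for mol in fits:
        if any((mol.x - k.x) ** 2 + (mol.y - k.y) ** 2 < 4.0 for k in kept):
            continue
        kept.append(mol)
    return kept


def count_spot(
    image: np.ndarray,
    spot_region: SpotRegion,
    params: DetectParams,
    *,
    mean_sm_intensity: float | None = None,
) -> SpotCount:
    """Count molecules on a circular spot, resolving or falling back to dense.

    In the resolved regime the count is the number of accepted fits inside
    the region.  When detection occupancy exceeds
    ``dense_occupancy_threshold`` the count is the total background-
    subtracted intensity in the region divided by the average integrated
    single-molecule intensity, which must be supplied (from resolved
    molecules of the same series or from a calibration set) — there is no
    silent default.
    """
    image = np.asarray(image, dtype=float)
    if not np.all(np.isfinite(image)):
        raise DataError("image contains non-finite pixels")
    mask = spot_region.mask(image.shape)
    total = float(image[mask].sum())
    footprint = np.pi * (2.0 * params.nominal_sigma) ** 2
    occupancy_per_det = footprint / spot_region.area_px

    def dense_count() -> SpotCount:
        if mean_sm_intensity is None or mean_sm_intensity <= 0:
            raise DenseCountError(
                "dense-regime count requires a positive mean single-molecule intensity"
            )
        n = int(round(total / mean_sm_intensity))
        return SpotCount(
            n_molecules=n,
            mode="dense",
            mean_sm_intensity=float(mean_sm_intensity),
            total_spot_intensity=total,
        )

    # cheap pre-check: candidate maxima count; clearly dense frames skip fitting
    noise = robust_noise_sd(image)
    thr = np.median(image) + params.local_max_threshold * max(noise, 1e-12)
    cand_x, cand_y = _local_maxima(image, thr)
    in_region = spot_region.contains(cand_x, cand_y)
    n_cand = int(np.count_nonzero(in_region))
    if n_cand * occupancy_per_det > 1.2 * params.dense_occupancy_threshold:
        return dense_count()

    detections = [
        m for m in detect_and_fit(image, params) if spot_region.contains(m.x, m.y)
    ]
    occupancy = len(detections) * occupancy_per_det
    if occupancy > params.dense_occupancy_threshold:
        return dense_count()

    if detections:
        med = float(np.median([integrated_intensity(m) for m in detections]))
    else:
        med = float(mean_sm_intensity) if mean_sm_intensity else 0.0
    return SpotCount(
        n_molecules=len(detections),
        mode="resolved",
        mean_sm_intensity=med,
        total_spot_intensity=total,
    )
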