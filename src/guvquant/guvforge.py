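"""Synthetic-data generator for the GUV quantification pipeline.

This module fabricates every input the analysis stages consume, together
with ground truth, so that the whole pipeline is testable without any
experimental data:

* vesicle populations with per-vesicle size, true encapsulation efficiency
  (EE) and true encapsulated copy number, including "ghost" (empty) and
  super-concentrated vesicles;
* wide-field fluorescence renderings of those populations (projection of a
  uniformly fluorescent sphere, Gaussian-blurred, with EMCCD-style noise);
* TIRF frames of single molecules captured on a circular microarray spot;
* calibration-standard series spanning 10 to 1e9 molecules per chamber,
  pushed through a saturable capture response.

Physical conventions
--------------------
Radii are in micrometres, volumes in picolitres (``V = 4/3 pi r^3 / 1000``
for ``r`` in um), concentrations in molecules per pL.  Pixel coordinates
are 0-based and row-major.  All stochasticity is driven by explicit seeds;
identical configuration and seed give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import gaussian_filter

from .errors import ConfigurationError, PlacementError
from .regions import SpotRegion

__all__ = [
    "PopulationConfig",
    "GUVTruth",
    "ImagingModel",
    "CalStandard",
    "CaptureModel",
    "WidefieldScene",
    "TirfFrame",
    "sample_population",
    "render_widefield",
    "render_tirf_frame",
    "make_standards",
    "simulate_capture",
    "radius_from_volume",
]

GHOST = "ghost"
NORMAL = "normal"
SUPERCONC = "superconcentrated"


def radius_from_volume(volume_pl: float) -> float:
    """Radius in um of a sphere of the given volume in pL."""
    return float((3.0 * volume_pl * 1000.0 / (4.0 * math.pi)) ** (1.0 / 3.0))


# ---------------------------------------------------------------------------
# population sampling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationConfig:
    """Parameters of a synthetic GUV population.

    The vesicle volume distribution is log-normal (``volume_median_pl``,
    geometric SD ``volume_gsd``), truncated to ``[volume_min_pl,
    volume_max_pl]``; the defaults span roughly 0.01-50 pL, the range seen
    in phase-transfer GUV preparations.  True EE is drawn from a truncated
    log-normal parameterised by its arithmetic mean and SD (as fractions);
    the default is right-skewed around ~11% spanning somewhat over a decade.
    ``seed_conc`` is the seed-solution concentration in molecules per pL.
    """

    n_guvs: int
    volume_median_pl: float = 0.7
    volume_gsd: float = 4.0
    volume_min_pl: float = 0.005
    volume_max_pl: float = 60.0
    seed_conc: float = 2.35e6
    ee_family: str = "lognormal"
    ee_mean: float = 0.114
    ee_sd: float = 0.062
    ee_low: float = 0.0
    ee_high: float = 1.0
    ghost_fraction: float = 0.0
    superconc_fraction: float = 0.0
    superconc_factor: float = 4.0
    rng_seed: int = 0

    def __post_init__(self):
        if self.n_guvs < 0:
            raise ConfigurationError("n_guvs must be >= 0")
        if self.volume_median_pl <= 0 or self.volume_gsd < 1.0:
            raise ConfigurationError("volume distribution parameters invalid")
        if not (0 < self.volume_min_pl < self.volume_max_pl):
            raise ConfigurationError("volume truncation bounds invalid")
        if self.seed_conc < 0:
            raise ConfigurationError("seed_conc must be >= 0")
        if self.ee_family not in ("lognormal", "normal"):
            raise ConfigurationError(f"unknown ee_family {self.ee_family!r}")
        if self.ee_mean <= 0 or self.ee_sd < 0:
            raise ConfigurationError("ee_mean must be > 0 and ee_sd >= 0")
        if not (0 <= self.ee_low < self.ee_high):
            raise ConfigurationError("EE truncation bounds invalid")
        for name in ("ghost_fraction", "superconc_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.ghost_fraction + self.superconc_fraction > 1.0:
            raise ConfigurationError("ghost_fraction + superconc_fraction must be <= 1")
        if self.superconc_factor <= 1.0:
            raise ConfigurationError("superconc_factor must be > 1")


@dataclass(frozen=True)
class GUVTruth:
    """Ground truth for one simulated vesicle."""

    id: int
    radius_um: float
    volume_pl: float
    true_ee: float
    true_copies: int
    klass: str = NORMAL


def _draw_truncated_lognormal(rng, mean, sd, low, high, size):
    """Truncated log-normal with the given *arithmetic* mean and SD.

    The underlying normal parameters are matched to the untruncated moments;
    with the default mild truncation the moment shift is negligible.
    """
    if sd == 0:
        return np.full(size, mean)
    sigma2 = math.log(1.0 + (sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    sigma = math.sqrt(sigma2)
    out = np.empty(size)
    pending = np.arange(size)
    for _ in range(1000):
        draw = rng.lognormal(mu, sigma, size=pending.size)
        ok = (draw > low) & (draw <= high)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise ConfigurationError("EE truncation bounds reject essentially all draws")


def _draw_truncated_normal(rng, mean, sd, low, high, size):
    if sd == 0:
        return np.full(size, mean)
    out = np.empty(size)
    pending = np.arange(size)
    for _ in range(1000):
        draw = rng.normal(mean, sd, size=pending.size)
        ok = (draw > low) & (draw <= high)
        out[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            return out
    raise ConfigurationError("EE truncation bounds reject essentially all draws")


def sample_population(cfg: PopulationConfig) -> list[GUVTruth]:
    """Draw a GUV population with ground-truth EE and copy numbers.

    Normal vesicles receive ``true_copies ~ Poisson(true_ee * seed_conc *
    volume)`` (zero-truncated so that only ghosts carry zero copies);
    ghosts get zero copies; super-concentrated vesicles have their EE
    multiplied by ``superconc_factor`` before the draw and may exceed 100%.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n = cfg.n_guvs
    if n == 0:
        return []

    # volumes: truncated log-normal
    sigma_v = math.log(cfg.volume_gsd)
    vols = np.empty(n)
    pending = np.arange(n)
    for _ in range(1000):
        draw = cfg.volume_median_pl * np.exp(rng.normal(0.0, sigma_v, size=pending.size))
        ok = (draw >= cfg.volume_min_pl) & (draw <= cfg.volume_max_pl)
        vols[pending[ok]] = draw[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:  # pragma: no cover - pathological truncation
        raise ConfigurationError("volume truncation bounds reject essentially all draws")

    # class assignment
    u = rng.random(n)
    klass = np.full(n, NORMAL, dtype=object)
    klass[u < cfg.ghost_fraction] = GHOST
    klass[(u >= cfg.ghost_fraction) & (u < cfg.ghost_fraction + cfg.superconc_fraction)] = SUPERCONC

    draw_ee = _draw_truncated_lognormal if cfg.ee_family == "lognormal" else _draw_truncated_normal
    ee = draw_ee(rng, cfg.ee_mean, cfg.ee_sd, cfg.ee_low, cfg.ee_high, n)
    ee = np.where(klass == SUPERCONC, ee * cfg.superconc_factor, ee)
    ee = np.where(klass == GHOST, 0.0, ee)

    lam = ee * cfg.seed_conc * vols
    copies = rng.poisson(lam).astype(np.int64)
    # zero-truncate normal/superconcentrated vesicles: only ghosts are empty
    needs = (klass != GHOST) & (copies == 0) & (lam > 0)
    for _ in range(100):
        if not needs.any():
            break
        copies[needs] = rng.poisson(lam[needs])
        needs = needs & (copies == 0)
    copies[needs] = 1

    out = []
    for i in range(n):
        v = float(vols[i])
        out.append(
            GUVTruth(
                id=i,
                radius_um=radius_from_volume(v),
                volume_pl=v,
                true_ee=float(ee[i]),
                true_copies=int(copies[i]),
                klass=str(klass[i]),
            )
        )
    return out


# ---------------------------------------------------------------------------
# imaging models
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ImagingModel:
    """EMCCD acquisition model shared by the TIRF and wide-field renderers.

    ``photons_per_molecule`` is the expected number of photons collected per
    molecule over the exposure; ``em_gain`` converts photons to camera counts;
    read noise is additive Gaussian in counts; ``baseline`` is the camera
    offset.  Pixel counts are ``baseline + em_gain * Poisson(lambda) +
    N(0, read_noise_sd)``, a gain-scaled Poisson model adequate for testing
    counting robustness (no explicit EM-register cascade).
    """

    pixel_size: float = 0.266  # um per px
    psf_sigma: float = 1.3  # px
    photons_per_molecule: float = 600.0
    em_gain: float = 30.0
    read_noise_sd: float = 60.0  # counts
    baseline: float = 500.0  # counts; well clear of zero so digitisation never clips noise
    frame_shape: tuple[int, int] = (512, 512)

    def __post_init__(self):
        for name in ("pixel_size", "photons_per_molecule", "em_gain", "read_noise_sd", "baseline"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be strictly positive")
        if self.psf_sigma < 0.5:
            raise ConfigurationError("psf_sigma must be >= 0.5 px")
        if len(self.frame_shape) != 2 or min(self.frame_shape) < 8:
            raise ConfigurationError("frame_shape must be (rows, cols) with size >= 8")

    def with_(self, **kw) -> "ImagingModel":
        return replace(self, **kw)


def _digitize(counts: np.ndarray) -> np.ndarray:
    return np.clip(np.rint(counts), 0, 65535).astype(np.uint16)


def _apply_camera(lam: np.ndarray, model: ImagingModel, rng, noise: bool) -> np.ndarray:
    """Photon-rate image -> camera counts (float, before digitisation)."""
    if noise:
        img = model.baseline + model.em_gain * rng.poisson(lam).astype(float)
        img += rng.normal(0.0, model.read_noise_sd, size=lam.shape)
    else:
        img = model.baseline + model.em_gain * lam
    return img


# ---------------------------------------------------------------------------
# wide-field rendering
# ---------------------------------------------------------------------------


@dataclass
class WidefieldScene:
    """A rendered wide-field tile with its pixel-level placement truth."""

    image: np.ndarray  # uint16
    positions: np.ndarray  # (n, 2) float, (x_px, y_px) centres, ghosts included
    guv_ids: np.ndarray  # (n,) int
    radii_px: np.ndarray  # (n,) float


def _place_vesicles(radii_px, shape, rng, margin_px, min_gap_px, max_tries):
    """Uniform random non-overlapping placement; larger vesicles placed first."""
    order = np.argsort(radii_px)[::-1]
    xs = np.empty(len(radii_px))
    ys = np.empty(len(radii_px))
    placed_x, placed_y, placed_r = [], [], []
    for idx in order:
        r = radii_px[idx]
        lo_x, hi_x = r + margin_px, shape[1] - 1 - r - margin_px
        lo_y, hi_y = r + margin_px, shape[0] - 1 - r - margin_px
        if hi_x <= lo_x or hi_y <= lo_y:
            raise PlacementError(f"vesicle of radius {r:.1f} px does not fit the field")
        for _ in range(max_tries):
            x = rng.uniform(lo_x, hi_x)
            y = rng.uniform(lo_y, hi_y)
            if placed_x:
                d2 = (np.array(placed_x) - x) ** 2 + (np.array(placed_y) - y) ** 2
                lim = (np.array(placed_r) + r + min_gap_px) ** 2
                if np.any(d2 < lim):
                    continue
            break
        else:
            raise PlacementError(
                f"could not place {len(radii_px)} vesicles in a "
                f"{shape[0]}x{shape[1]} field after {max_tries} tries"
            )
        placed_x.append(x)
        placed_y.append(y)
        placed_r.append(r)
        xs[idx], ys[idx] = x, y
    return xs, ys


def render_widefield(
    pop: list[GUVTruth],
    model: ImagingModel,
    rng_seed: int,
    *,
    positions: np.ndarray | None = None,
    noise: bool = True,
    blur: bool = True,
    margin_px: float = 4.0,
    min_gap_px: float = 6.0,
    max_tries: int = 2000,
    halo_amplitude: float = 0.0,
    halo_sigma_px: float = 2.0,
) -> WidefieldScene:
    """Render a population into one wide-field fluorescence tile.

    Each vesicle is drawn as the projection of a uniformly fluorescent
    sphere: the per-pixel photon rate is proportional to the chord length
    ``2 sqrt(r^2 - d^2)`` through the sphere, normalised so that the total
    expected photon count of a vesicle is exactly ``true_copies *
    photons_per_molecule`` (photometric mass conservation).  The rate image
    is then Gaussian-blurred by the PSF and passed through the camera model.
    Ghost vesicles carry no fluorophores and contribute nothing to the
    image; their positions are still recorded in the truth table.

    An optional additive halo ring (a Gaussian shell at the membrane radius)
    emulates the out-of-focus halo of real GUV images; it is off by default.
    """
    rng = np.random.default_rng(rng_seed)
    shape = model.frame_shape
    radii_px = np.array([g.radius_um / model.pixel_size for g in pop])
    if len(pop) and radii_px.min() < 2.0:
        raise ConfigurationError("all vesicles must have radius >= 2 px at this pixel size")

    if positions is None and len(pop):
        xs, ys = _place_vesicles(radii_px, shape, rng, margin_px, min_gap_px, max_tries)
    elif len(pop):
        positions = np.asarray(positions, dtype=float)
        xs, ys = positions[:, 0], positions[:, 1]
    else:
        xs = ys = np.empty(0)

    lam = np.zeros(shape, dtype=float)
    for g, x0, y0, r in zip(pop, xs, ys, radii_px):
        if g.true_copies == 0 and halo_amplitude == 0.0:
            continue
        pad = int(math.ceil(r + 4 * model.psf_sigma + 3 * halo_sigma_px)) + 2
        x_lo, x_hi = max(0, int(x0) - pad), min(shape[1], int(x0) + pad + 1)
        y_lo, y_hi = max(0, int(y0) - pad), min(shape[0], int(y0) + pad + 1)
        yy, xx = np.mgrid[y_lo:y_hi, x_lo:x_hi]
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        if g.true_copies > 0:
            chord = np.sqrt(np.clip(r**2 - d2, 0.0, None))
            total = chord.sum()
            if total > 0:
                lam[y_lo:y_hi, x_lo:x_hi] += (
                    g.true_copies * model.photons_per_molecule / total
                ) * chord
        if halo_amplitude > 0.0:
            d = np.sqrt(d2)
            lam[y_lo:y_hi, x_lo:x_hi] += halo_amplitude * np.exp(
                -((d - r) ** 2) / (2.0 * halo_sigma_px**2)
            )

    if blur:
        lam = gaussian_filter(lam, model.psf_sigma, mode="constant")
    img = _apply_camera(lam, model, rng, noise)
    return WidefieldScene(
        image=_digitize(img),
        positions=np.column_stack([xs, ys]) if len(pop) else np.empty((0, 2)),
        guv_ids=np.array([g.id for g in pop], dtype=int),
        radii_px=radii_px,
    )


# ---------------------------------------------------------------------------
# TIRF rendering
# ---------------------------------------------------------------------------


@dataclass
class TirfFrame:
    """A rendered TIRF frame with ground-truth emitter positions.

    ``exposure_scale`` is the attenuation applied before photon detection
    (auto-exposure for very bright spots so counts fit 16 bits); analysis
    must divide measured intensities by it.
    """

    image: np.ndarray  # uint16
    positions: np.ndarray  # (n, 2) float32, (x_px, y_px)
    exposure_scale: float
    n_molecules: int


# above this count, molecules are binned to the pixel grid before PSF blur
_SPARSE_RENDER_LIMIT = 4000


def render_tirf_frame(
    n_molecules: int,
    model: ImagingModel,
    region: SpotRegion,
    rng_seed: int,
    *,
    noise: bool = True,
    exposure_scale: float | None = None,
    max_counts: float = 30000.0,
) -> TirfFrame:
    """Render ``n_molecules`` fluorophores uniformly scattered on a spot.

    Sparse frames are rendered per molecule with sub-pixel accuracy (each
    molecule contributes an isotropic Gaussian of width ``psf_sigma`` whose
    integral is ``photons_per_molecule``); very dense frames are binned to
    the pixel grid and blurred, which is indistinguishable at those
    densities and keeps rendering linear in the molecule count.
    """
    if n_molecules < 0:
        raise ConfigurationError("n_molecules must be >= 0")
    shape = model.frame_shape
    if not region.inside_frame(shape):
        raise ConfigurationError("spot region extends outside the frame")
    rng = np.random.default_rng(rng_seed)

    # uniform positions in the circular spot
    rr = region.radius_px * np.sqrt(rng.random(n_molecules))
    th = rng.uniform(0.0, 2.0 * np.pi, n_molecules)
    px = (region.cx + rr * np.cos(th)).astype(np.float32)
    py = (region.cy + rr * np.sin(th)).astype(np.float32)

    p = model.photons_per_molecule
    sig = model.psf_sigma
    lam = np.zeros(shape, dtype=float)
    if 0 < n_molecules <= _SPARSE_RENDER_LIMIT:
        w = int(math.ceil(4 * sig))
        amp = p / (2.0 * np.pi * sig**2)
        for x0, y0 in zip(px, py):
            xi, yi = int(round(float(x0))), int(round(float(y0)))
            x_lo, x_hi = max(0, xi - w), min(shape[1], xi + w + 1)
            y_lo, y_hi = max(0, yi - w), min(shape[0], yi + w + 1)
            gx = np.exp(-((np.arange(x_lo, x_hi) - x0) ** 2) / (2 * sig**2))
            gy = np.exp(-((np.arange(y_lo, y_hi) - y0) ** 2) / (2 * sig**2))
            lam[y_lo:y_hi, x_lo:x_hi] += amp * np.outer(gy, gx)
    elif n_molecules > 0:
        xi = np.clip(px.astype(np.int64), 0, shape[1] - 1)
        yi = np.clip(py.astype(np.int64), 0, shape[0] - 1)
        hist = np.bincount(yi * shape[1] + xi, minlength=shape[0] * shape[1]).reshape(shape)
        lam = gaussian_filter(hist.astype(float) * p, sig, mode="constant")

    if exposure_scale is None:
        peak = lam.max() * model.em_gain if n_molecules else 0.0
        exposure_scale = min(1.0, max_counts / peak) if peak > 0 else 1.0
    if not (0 < exposure_scale <= 1.0):
        raise ConfigurationError("exposure_scale must lie in (0, 1]")
    lam = lam * exposure_scale

    img = _apply_camera(lam, model, rng, noise)
    return TirfFrame(
        image=_digitize(img),
        positions=np.column_stack([px, py]) if n_molecules else np.empty((0, 2), np.float32),
        exposure_scale=float(exposure_scale),
        n_molecules=int(n_molecules),
    )


# ---------------------------------------------------------------------------
# calibration standards and the capture response
# ---------------------------------------------------------------------------


@dataclass
class CalStandard:
    """One calibration standard: a known number of molecules per chamber."""

    molecules_per_chamber: float
    replicate_id: int = 0
    observed_count: float | None = None  # filled after simulation / counting

    def __post_init__(self):
        if self.molecules_per_chamber < 0:
            raise ConfigurationError("molecules_per_chamber must be >= 0")


def make_standards(
    levels: list[float] | None = None, replicates: int = 1
) -> list[CalStandard]:
    """Build a standard series; the default is log-spaced from 10 to 1e9."""
    if replicates < 1:
        raise ConfigurationError("replicates must be >= 1")
    if levels is None:
        levels = np.logspace(1, 9, 9).tolist()
    return [
        CalStandard(molecules_per_chamber=float(level), replicate_id=rep)
        for level in levels
        for rep in range(replicates)
    ]


@dataclass(frozen=True)
class CaptureModel:
    """Saturable capture response of the microarray spot.

    Maps molecules released into the chamber to the expected number bound
    on the spot: a nonspecific-binding floor ``n_bkd``, a finite number of
    binding sites giving saturation at ``n_sat``, and a logistic transition
    (slope ``m``, inflection ``c``, asymmetry ``a``).  With the defaults
    the mid-range capture fraction is ~77% ("a high fraction of the total
    target being bound") and the background floor is 26 molecules per frame.
    """

    n_bkd: float = 26.0
    n_sat: float = 1.0e7
    m: float = 1.0
    c: float = 1.3e7
    a: float = 1.0

    def __post_init__(self):
        if not (self.n_sat > self.n_bkd >= 0):
            raise ConfigurationError("require n_sat > n_bkd >= 0")
        if self.m <= 0 or self.c <= 0 or self.a <= 0:
            raise ConfigurationError("m, c, a must be positive")

    def expected_bound(self, molecules_in_chamber):
        x = np.asarray(molecules_in_chamber, dtype=float)
        with np.errstate(divide="ignore"):
            y = np.where(
                x > 0,
                self.n_bkd
                + (self.n_sat - self.n_bkd) / (1.0 + (self.c / np.maximum(x, 1e-300)) ** self.m) ** self.a,
                self.n_bkd,
            )
        return y if y.ndim else float(y)


def simulate_capture(molecules_in_chamber: float, capture: CaptureModel, rng) -> int:
    """Number of molecules bound on the spot: Poisson around the response."""
    return int(rng.poisson(capture.expected_bound(molecules_in_chamber)))
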