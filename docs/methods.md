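# Methods

`guvquant` measures how much protein a giant unilamellar vesicle (GUV)
actually encapsulates, in absolute copy numbers, and expresses it as a
per-vesicle encapsulation efficiency (EE). This note describes the models
behind both halves of the package — the synthetic-data generator and the
analysis chain — the parameters that matter, the numerical choices, and
what the synthetic results do and do not demonstrate about real data.

## The measurement model

A GUV of volume `V` (pL) formed from a seed solution of concentration
`C` (molecules/pL) is *expected* to contain `C·V` molecules. The measured
interior copy number `N` defines

    EE (%) = 100 · N / (C · V)

Two instruments observe each vesicle:

* **Wide-field fluorescence** gives the vesicle radius (hence `V`) and an
  arbitrary-unit total fluorescence `I`.
* **A single-molecule microarray** gives `N`: the vesicle is isolated in a
  nanolitre chamber and lysed; released molecules bind a capture spot that
  is imaged by TIRF microscopy, single molecules are counted, and the
  count is converted to molecules-per-chamber through a calibration curve.

Both observables follow power laws in volume, `I = a_µ V^k` and
`N = a_SM V^k` with a common exponent `k` (constant interior concentration
implies `k = 1`), so the quotient `a_SM/a_µ` converts microscopy
intensities to absolute molecule numbers independently of volume. The
package fits both laws jointly in log-log space with a shared slope and
reports the two independent slopes as a diagnostic of that assumption.

### Calibration (5PL)

The spot's response to `x` molecules per chamber is the five-parameter
logistic

    y(x) = N_bkd + (N_sat − N_bkd) / (1 + (c/x)^m)^A

with background asymptote `N_bkd` (nonspecific binding, ~26 molecules per
frame), saturation `N_sat` (~1e7, the finite binding sites of the spot),
slope `m`, inflection `c` and asymmetry `A` (`A = 1` gives the symmetric
4PL). Fitting is nonlinear least squares on log10 counts vs log10 level,
with asymptote-anchored initialisation (`N_bkd` ← smallest count, `N_sat`
← largest, `c` ← mid-log level, `m = A = 1`), so identical standards give
identical curves. Standards span 10–1e9 molecules per chamber.

The inverse is closed-form:

    x = c · [ ((N_sat − N_bkd)/(y − N_bkd))^(1/A) − 1 ]^(−1/m)

Counts at or below `N_bkd` are *censored at the limit of detection* — they
become flagged NaN records, never zeros, and are excluded from batch means
but counted separately. Counts at or above `N_sat` raise an error.
Inversions outside the fitted standards' range are flagged extrapolated.

A property worth stating: any *count-dependent* bias of the counting stage
(e.g. the ~1% PSF leakage out of the spot region, or the mild undercount
of nearly-merged molecules in the resolved regime) cancels through the
calibration, because standards and samples are counted by the same
procedure and the fitted curve maps observed counts, not ideal ones.

## The synthetic-data generator

The generator exists so that every stage is testable against ground truth.

**Population.** Vesicle volumes are log-normal (survey default: median
0.7 pL, geometric SD 4.0, truncated to 0.005–60 pL, matching the ~0.01–50
pL span of phase-transfer preparations; the shipped replication config
uses median 0.35 pL, GSD 3.2, truncated 0.008–20 pL for the
trapped-and-lysed subset). True EE is a truncated log-normal on (0, 1]
parameterised by its arithmetic mean and SD — 0.114 and 0.062 in the
replication config — the right-skewed, decade-spanning shape these
preparations show. True copy numbers are Poisson around `EE·C·V`,
zero-truncated so that only *ghost* vesicles (an explicit class, default
2%) are empty. *Super-concentrated* vesicles (default off) have their EE
multiplied by a factor > 1 before the draw and may exceed 100%.

**Wide-field rendering.** A uniformly fluorescent sphere projects onto the
focal plane with per-pixel intensity proportional to the chord length
`2√(r²−d²)`. The profile is normalised so a vesicle's total expected
photon count is exactly `copies × photons_per_molecule` (photometric mass
conservation, exact by construction), blurred by a Gaussian PSF, and
passed through the camera model. An optional additive membrane-halo ring
exists but is off by default.

**TIRF rendering.** Molecules land uniformly on the circular spot. Sparse
frames (≤ 4000 molecules) are rendered per molecule with sub-pixel
Gaussian PSFs; denser frames are binned to the pixel grid before the PSF
blur, which is indistinguishable at those densities and keeps rendering
linear in count. The number of molecules reaching the spot follows the
same saturable 5PL-shaped capture response used for standards (mid-range
capture fraction ~77%), with Poisson binding noise.

**Camera model.** `counts = baseline + gain · Poisson(λ) + N(0, read_sd)`,
digitised to 16 bits — a gain-scaled Poisson EMCCD model without the
EM-register cascade, sufficient for testing counting robustness. The TIRF
baseline is 500 counts so digitisation never clips the noise floor. Very
bright frames are attenuated by a recorded `exposure_scale` (auto-exposure)
so 16-bit TIFFs never saturate; analysis divides it back out.

Everything is driven by one seed through a `SeedSequence` spawn tree:
identical config + seed ⇒ bit-identical fixtures.

## Analysis choices

**Offset removal.** The simulated camera offset is spatially flat, so the
pipeline subtracts a robust median (off-spot pixels for TIRF frames, whole
tile for wide-field) *without clipping*: dense-mode counting sums ~1e5
pixels, where the order-statistic bias of a morphological background
estimate, or the positive bias of clipping noise at zero, would masquerade
as hundreds of molecules. The generic `flatten_field` and rolling-ball
`subtract_background` operations remain available for structured real-data
backgrounds.

**Detection and fitting.** Local maxima above 5 robust noise SDs are fit
with isotropic 2D Gaussians (5 parameters, analytic Jacobian) in a window
sized to the widest acceptable PSF. Two measures keep crowded fits honest:
each candidate's fit sees only the pixels *it owns* (closer to it than to
any other candidate), so neighbouring molecules cannot drag two fits onto
a shared midpoint; and fit positions are constrained to ±1.5 px of their
candidate peak. Candidates within 2 px of a stronger one are suppressed,
and fits closer than 2 px are merged keeping the lower residual — 2 px is
the practical resolving limit of a 1.3 px PSF, below which a second
detection is the same emitter's noise shoulder. Accepted fits must satisfy
0.5–2.5× the nominal PSF width and a minimum amplitude.

**Resolved vs dense counting.** Each detection is assigned a footprint of
radius `2σ_nom`; when footprints would cover more than 10% of the spot,
the spot is counted as total background-subtracted intensity divided by
the median integrated single-molecule intensity (`amplitude·2πσ²`) of
resolved molecules from the calibration series. The median (rather than
the mean) is robust to the occasional merged-pair fit. Dense mode without
a single-molecule reference is an explicit error, never a silent default.
On simulated frames the two modes agree within ~5% around the switch.

**Vesicle radius.** The in-focus image of a projected sphere is not a flat
disk: thresholding at a fraction `f` of the peak cuts the region at
`r√(1−f²)`, so a naive area-equivalent radius underestimates `r` by 13%
already at half-peak — an error that *cubes* into volume and hence EE.
Measurement therefore (a) re-thresholds each vesicle at half its own
smoothed peak and divides the equivalent-circle radius by the half-peak
crossing of the *blurred* projected-sphere profile, computed numerically
for the known PSF width and cached; and (b) below ~8 px, where pixel-count
granularity dominates, switches to the flux/peak relation of the projected
sphere, `F/I0 = (2/3)πr²`, with numeric corrections for blur attenuation
of the peak and for the flux fraction outside the segmentation threshold
contour. Monte-Carlo on single vesicles puts the radius error at ≲1%
(bright) to ≲4% (dimmest, smallest), i.e. volume within ~12% worst-case.

**Segmentation.** Smoothing, a threshold (global Otsu, or fixed — the
replication config uses a fixed low threshold at ~8 smoothed-noise SDs so
dim vesicles are not selectively dropped, which would bias the EE mean
upward), connected components, radius and circularity filters, and an
optional watershed split of touching vesicles. The watershed seeds come
from h-maxima of a *smoothed* distance transform with a deep-saddle
requirement (h ≥ 2 px), because boundary noise otherwise shatters single
vesicles. Ghost vesicles contain no fluorophore and are invisible to
fluorescence-channel segmentation — a real limitation of the modality,
reproduced rather than hidden; they are accounted as a separate fraction,
not as EE = 0 records.

**Matching.** Simulated analyses join chamber counts to segmented vesicles
through the operator's stage log (trap positions per tile) by nearest
centroid — never through the truth tables.

**Batch statistics.** Sample SD, linear-interpolation quartiles, Tukey
whiskers (most extreme values within 1.5 IQR of the quartiles), outliers
beyond, and the dynamic-range span `log10(max/min)`. Censored records are
excluded and reported separately.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `seed_conc` | 2.35e6 | molecules/pL | seed-solution concentration of the replication study |
| `ee_mean`, `ee_sd` | 0.114, 0.062 | fraction | replication EE distribution (truncated log-normal) |
| `ghost_fraction` | 0.02 | — | few-percent empty vesicles seen in these preparations |
| `capture_n_bkd` | 26 | molecules | nonspecific binding floor per frame |
| `capture_n_sat` | 1e7 | molecules | spot binding-site ceiling |
| `tirf_pixel_size_um` | 0.266 | µm/px | 16 µm EMCCD pixels behind a 60× objective |
| `tirf_psf_sigma_px` | 1.3 | px | diffraction-limited PSF at 488 nm |
| `spot_radius_px` | 180 | px | a ~100 µm-class capture spot at this pixel size |
| `tirf_photons_per_molecule` | 600 | photons | bright single-molecule imaging; SNR ≈ 28 against read noise |
| `dense_occupancy_threshold` | 0.10 | — | resolved/dense switch; modes agree within 15% around it |
| `wf_fixed_threshold` | 25 | counts | ~8 smoothed-noise SDs; keeps the dimmest vesicles |
| `standard_n_levels` | 13 | — | log-spaced 10–1e9; covers the resolved→dense transition |

Problem sizes: the replication study is 8 batches × 120 GUVs (512×512
frames throughout, 10 wide-field tiles per batch, 13×3 standards), chosen
as the full study design; it simulates and analyses in a few minutes on
one CPU. Property tests use single vesicles, single frames, or 1×40-GUV
batches.

## What passing tests show — and what they don't

The generator emulates: heterogeneous vesicle sizes and loadings, ghosts,
super-concentration, saturable capture with background binding, Poisson
photon statistics, gain and read noise, auto-exposure, and the sparse and
dense counting regimes. It does **not** emulate: membrane halos (off by
default), out-of-focus light, illumination gradients (the flattening op is
tested on constructed vignettes instead), stage drift, photobleaching,
semifused vesicle clusters, non-spherical vesicles, or chamber transport
kinetics (capture is an equilibrium response). Recovery of the generator's
EE distribution therefore demonstrates the *estimator chain* is unbiased
under the stated imaging model, not that real micrographs are this clean.
The bright-field cross-check of segmentation used on real data is out of
scope here.

## Known limitations

* Ghost vesicles are invisible to the fluorescence-only pipeline; the
  reported EE statistics condition on detectable vesicles.
* The radius corrections assume spherical vesicles and a known PSF width;
  an error in the assumed PSF propagates ~quadratically but weakly
  (sub-percent for σ misestimated by 20% at r ≥ 8 px).
* The 5PL's `c`–`A` tradeoff leaves individual-parameter estimates of the
  inflection noisy (~10% SD at 10% count noise) even when the fitted curve
  — and therefore every inversion — is accurate.
* EE > 100% is flagged, not explained: the generator can produce
  super-concentrated vesicles, but the pipeline makes no mechanistic claim
  about them.
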