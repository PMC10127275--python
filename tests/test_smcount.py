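"""Tests of single-molecule detection, fitting and spot counting."""

import numpy as np
import pytest
from scipy.spatial import cKDTree

from guvquant import guvforge, smcount
from guvquant.errors import ConfigurationError, DataError, DenseCountError
from guvquant.regions import SpotRegion

from conftest import subtract_offset


def gaussian_peak(shape, x0, y0, amp, sigma, offset=0.0):
    yy, xx = np.mgrid[: shape[0], : shape[1]].astype(float)
    return offset + amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sigma**2))


class TestFlattenField:
    def test_constant_profile_is_identity(self, rng):
        img = rng.normal(100, 5, (64, 64))
        out = smcount.flatten_field(img, np.full((64, 64), 3.7))
        assert np.allclose(out, img)

    def test_profile_scale_invariance(self, rng):
        img = rng.normal(100, 5, (64, 64))
        prof = 1.0 + 0.3 * rng.random((64, 64))
        assert np.allclose(
            smcount.flatten_field(img, prof), smcount.flatten_field(img, 2.0 * prof)
        )

    def test_vignette_restored(self, rng):
        yy, xx = np.mgrid[:256, :256].astype(float)
        vignette = 1.0 - 0.4 * (((xx - 128) ** 2 + (yy - 128) ** 2) / 128**2 / 2)
        flat_truth = np.full((256, 256), 1000.0)
        observed = flat_truth * vignette + rng.normal(0, 2, (256, 256))
        restored = smcount.flatten_field(observed, vignette)
        corner = restored[:32, :32].mean()
        centre = restored[112:144, 112:144].mean()
        assert corner / centre == pytest.approx(1.0, abs=0.02)

    def test_nonpositive_profile_rejected(self):
        with pytest.raises(ConfigurationError):
            smcount.flatten_field(np.ones((8, 8)), np.zeros((8, 8)))


class TestSubtractBackground:
    def test_constant_image_zeroed(self):
        out = smcount.subtract_background(np.full((64, 64), 250.0), radius=8)
        assert np.allclose(out, 0.0)

    def test_peak_amplitude_preserved(self):
        img = gaussian_peak((64, 64), 32, 32, amp=500.0, sigma=1.3, offset=200.0)
        out = smcount.subtract_background(img, radius=8)
        assert out.max() == pytest.approx(500.0, rel=0.05)

    def test_output_clipped_at_zero(self, rng):
        img = rng.normal(100, 20, (64, 64))
        assert smcount.subtract_background(img, radius=5).min() >= 0.0

    def test_invalid_radius(self):
        with pytest.raises(ConfigurationError):
            smcount.subtract_background(np.ones((8, 8)), radius=0)


class TestDetectAndFit:
    def test_blank_frames_yield_almost_no_detections(self, tirf_model, spot, detect_params):
        # false-positive budget: well under one detection per frame
        total = 0
        for seed in range(25):
            fr = guvforge.render_tirf_frame(0, tirf_model, spot, 900 + seed)
            total += len(smcount.detect_and_fit(subtract_offset(fr.image), detect_params))
        assert total <= 1

    def test_single_molecule_localised_subpixel(self, detect_params):
        # amplitude ~500 counts at unit gain (~5300 photons), PSF sigma 1.3 px
        model = guvforge.ImagingModel(
            photons_per_molecule=500 * 2 * np.pi * 1.3**2,
            em_gain=1.0, read_noise_sd=10.0, frame_shape=(128, 128),
        )
        region = SpotRegion(cx=63.5, cy=63.5, radius_px=40.0)
        hits, sigmas = 0, []
        for seed in range(10):
            fr = guvforge.render_tirf_frame(1, model, region, seed)
            dets = smcount.detect_and_fit(subtract_offset(fr.image), detect_params)
            assert len(dets) == 1
            (d,) = dets
            x0, y0 = fr.positions[0]
            if abs(d.x - x0) < 0.2 and abs(d.y - y0) < 0.2:
                hits += 1
            sigmas.append(d.sigma)
        assert hits >= 9
        # ~177 photons per molecule put the shot-noise limit on a single
        # width estimate near 8%; the ensemble mean must be unbiased
        assert np.mean(sigmas) == pytest.approx(1.3, rel=0.15)

    def test_two_separated_molecules_both_found(self, tirf_model, detect_params):
        sep = 4 * tirf_model.psf_sigma
        img = gaussian_peak((64, 64), 30.0, 30.0, 1700.0, 1.3)
        img += gaussian_peak((64, 64), 30.0 + sep, 30.0, 1700.0, 1.3)
        dets = smcount.detect_and_fit(img + np.random.default_rng(0).normal(0, 30, (64, 64)),
                                      detect_params)
        assert len(dets) == 2

    def test_nonfinite_pixels_rejected(self, detect_params):
        img = np.zeros((32, 32))
        img[5, 5] = np.nan
        with pytest.raises(DataError):
            smcount.detect_and_fit(img, detect_params)

    def test_fit_window_invariant_enforced(self):
        with pytest.raises(ConfigurationError):
            smcount.DetectParams(fit_window=7, min_sigma=0.65, max_sigma=3.25)


class TestCountSpot:
    def test_fifty_sparse_molecules(self, tirf_model, spot, detect_params):
        for seed in (0, 4, 5):
            fr = guvforge.render_tirf_frame(50, tirf_model, spot, seed)
            sc = smcount.count_spot(subtract_offset(fr.image), spot, detect_params)
            assert sc.mode == "resolved"
            assert abs(sc.n_molecules - 50) <= 2

    def test_empty_spot(self, tirf_model, spot, detect_params):
        fr = guvforge.render_tirf_frame(0, tirf_model, spot, 31)
        sc = smcount.count_spot(subtract_offset(fr.image), spot, detect_params)
        assert sc.mode == "resolved" and sc.n_molecules == 0

    def test_dense_count_is_total_over_mean_intensity(self, tirf_model, spot, detect_params):
        fr = guvforge.render_tirf_frame(5000, tirf_model, spot, 32)
        img = subtract_offset(fr.image) / fr.exposure_scale
        sc = smcount.count_spot(img, spot, detect_params, mean_sm_intensity=500.0)
        assert sc.mode == "dense"
        assert sc.n_molecules == round(sc.total_spot_intensity / 500.0)

    def test_dense_without_reference_raises(self, tirf_model, spot, detect_params):
        fr = guvforge.render_tirf_frame(5000, tirf_model, spot, 33)
        with pytest.raises(DenseCountError):
            smcount.count_spot(subtract_offset(fr.image), spot, detect_params)

    def test_expected_count_monotone_in_truth(self, tirf_model, spot, detect_params):
        means = []
        for n in (10, 60, 150):
            counts = [
                smcount.count_spot(
                    subtract_offset(guvforge.render_tirf_frame(n, tirf_model, spot, 40 + s).image),
                    spot, detect_params,
                ).n_molecules
                for s in range(2)
            ]
            means.append(np.mean(counts))
        assert means[0] < means[1] < means[2]

    def test_dense_and_resolved_agree_near_threshold(self, tirf_model, spot, detect_params):
        # establish the single-molecule intensity from a sparse frame
        sparse = guvforge.render_tirf_frame(100, tirf_model, spot, 50)
        ref = smcount.count_spot(subtract_offset(sparse.image), spot, detect_params)
        for n in (350, 450):
            fr = guvforge.render_tirf_frame(n, tirf_model, spot, 60 + n)
            img = subtract_offset(fr.image)
            resolved = [
                d for d in smcount.detect_and_fit(img, detect_params)
                if spot.contains(d.x, d.y)
            ]
            dense = img[spot.mask(img.shape)].sum() / ref.mean_sm_intensity
            assert len(resolved) == pytest.approx(dense, rel=0.15)


class TestSparseRecallPrecision:
    def test_recall_and_precision_on_sparse_frames(self, tirf_model, spot, detect_params):
        # ~0.02 molecules per um^2 at 0.266 um/px over the spot area
        area_um2 = np.pi * (spot.radius_px * tirf_model.pixel_size) ** 2
        n = int(0.02 * area_um2)
        tp = fp = fn = 0
        for seed in range(6):
            fr = guvforge.render_tirf_frame(n, tirf_model, spot, 200 + seed)
            dets = smcount.detect_and_fit(subtract_offset(fr.image), detect_params)
            pts = np.array([[d.x, d.y] for d in dets])
            d, _ = cKDTree(pts).query(fr.positions, k=1)
            hits = int(np.sum(d < 1.5))
            tp += hits
            fn += n - hits
            fp += len(dets) - hits
        recall = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert recall >= 0.95
        assert precision >= 0.95
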