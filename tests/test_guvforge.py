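"""Tests of the synthetic-data generator: populations, renderers, standards."""

import dataclasses
import math

import numpy as np
import pytest

from guvquant import guvforge
from guvquant.errors import ConfigurationError, PlacementError
from guvquant.regions import SpotRegion

from conftest import subtract_offset


def pop_cfg(**kw):
    base = dict(n_guvs=50, rng_seed=11)
    base.update(kw)
    return guvforge.PopulationConfig(**base)


class TestSamplePopulation:
    def test_empty_population(self):
        assert guvforge.sample_population(pop_cfg(n_guvs=0)) == []

    def test_survey_population_size(self):
        # a survey-sized draw of the kind used for whole-slide statistics
        pop = guvforge.sample_population(pop_cfg(n_guvs=2158))
        assert len(pop) == 2158
        vols = np.array([g.volume_pl for g in pop])
        assert vols.min() >= 0.005 and vols.max() <= 60.0

    def test_all_ghosts_have_zero_copies(self):
        pop = guvforge.sample_population(pop_cfg(ghost_fraction=1.0))
        assert all(g.klass == "ghost" and g.true_copies == 0 for g in pop)

    def test_only_ghosts_are_empty(self):
        pop = guvforge.sample_population(pop_cfg(n_guvs=500, ghost_fraction=0.3))
        for g in pop:
            assert (g.true_copies == 0) == (g.klass == "ghost")

    def test_volume_radius_consistency(self):
        for g in guvforge.sample_population(pop_cfg()):
            assert g.volume_pl == pytest.approx(
                (4 / 3) * math.pi * g.radius_um**3 / 1000, rel=1e-12
            )

    def test_determinism(self):
        a = guvforge.sample_population(pop_cfg())
        b = guvforge.sample_population(pop_cfg())
        assert a == b

    def test_copy_number_conservation(self):
        # fixed volume and EE: mean copies must approach ee * C * V
        cfg = pop_cfg(
            n_guvs=4000, volume_median_pl=0.5, volume_gsd=1.0, ee_sd=0.0, ee_mean=0.1,
            seed_conc=1.0e5,
        )
        pop = guvforge.sample_population(cfg)
        lam = 0.1 * 1.0e5 * 0.5
        mean = np.mean([g.true_copies for g in pop])
        assert mean == pytest.approx(lam, abs=4 * math.sqrt(lam / 4000))

    def test_superconcentration_multiplies_ee(self):
        cfg = pop_cfg(superconc_fraction=1.0, superconc_factor=4.0, ee_sd=0.0)
        pop = guvforge.sample_population(cfg)
        assert all(g.true_ee == pytest.approx(4 * 0.114) for g in pop)

    @pytest.mark.parametrize(
        "bad",
        [
            dict(ghost_fraction=0.7, superconc_fraction=0.6),
            dict(ghost_fraction=-0.1),
            dict(seed_conc=-1.0),
            dict(superconc_factor=0.5),
            dict(volume_gsd=0.9),
            dict(ee_family="gamma"),
        ],
    )
    def test_invalid_config_rejected(self, bad):
        with pytest.raises(ConfigurationError):
            pop_cfg(**bad)


def single_vesicle(volume_pl, copies, ee=0.1):
    r = guvforge.radius_from_volume(volume_pl)
    return guvforge.GUVTruth(0, r, volume_pl, ee, copies, "normal")


class TestRenderWidefield:
    def test_empty_population_is_baseline(self, wf_model):
        scene = guvforge.render_widefield([], wf_model, 1)
        img = scene.image.astype(float)
        assert img.mean() == pytest.approx(wf_model.baseline, abs=1.0)
        assert img.std() < 4 * (wf_model.read_noise_sd + math.sqrt(wf_model.baseline))

    def test_mass_conservation_noiseless(self, wf_model):
        # blur-free, noise-free: total signal equals copies * photons exactly
        g = single_vesicle(1.0, 100_000)
        scene = guvforge.render_widefield(
            [g], wf_model, 1, noise=False, blur=False, positions=[[200.0, 200.0]]
        )
        total = (scene.image.astype(float) - wf_model.baseline).sum()
        expect = 100_000 * wf_model.photons_per_molecule * wf_model.em_gain
        assert total == pytest.approx(expect, rel=1e-3)

    def test_signal_per_copy_volume_invariant(self, wf_model):
        totals = {}
        for v, copies in [(0.1, 20_000), (10.0, 20_000)]:
            scene = guvforge.render_widefield(
                [single_vesicle(v, copies)], wf_model, 2, noise=False,
                positions=[[255.0, 255.0]],
            )
            totals[v] = (scene.image.astype(float) - wf_model.baseline).sum() / copies
        assert totals[0.1] == pytest.approx(totals[10.0], rel=0.01)

    def test_doubling_copies_doubles_signal(self, wf_model):
        sums = []
        for copies in (30_000, 60_000):
            scene = guvforge.render_widefield(
                [single_vesicle(1.0, copies)], wf_model, 3, noise=False,
                positions=[[255.0, 255.0]],
            )
            sums.append((scene.image.astype(float) - wf_model.baseline).sum())
        # within the quantisation of the 16-bit image
        assert sums[1] == pytest.approx(2 * sums[0], rel=1e-4)

    def test_ghost_renders_nothing(self, wf_model):
        g = guvforge.GUVTruth(0, guvforge.radius_from_volume(1.0), 1.0, 0.0, 0, "ghost")
        scene = guvforge.render_widefield([g], wf_model, 4, noise=False)
        assert (scene.image.astype(float) - wf_model.baseline).max() == pytest.approx(0.0)

    def test_too_small_vesicle_rejected(self, wf_model):
        tiny = single_vesicle(1e-4, 100)  # radius under 2 px
        with pytest.raises(ConfigurationError):
            guvforge.render_widefield([tiny], wf_model, 5)

    def test_placement_failure_is_bounded(self, wf_model):
        big = [single_vesicle(20.0, 1000) for _ in range(40)]
        pop = [dataclasses.replace(g, id=i) for i, g in enumerate(big)]
        with pytest.raises(PlacementError):
            guvforge.render_widefield(pop, wf_model, 6, max_tries=50)


class TestRenderTirf:
    def test_zero_molecules_baseline_only(self, tirf_model, spot):
        fr = guvforge.render_tirf_frame(0, tirf_model, spot, 1)
        img = fr.image.astype(float)
        assert fr.positions.shape == (0, 2)
        assert img.mean() == pytest.approx(tirf_model.baseline, abs=2.0)
        assert img.std() == pytest.approx(tirf_model.read_noise_sd, rel=0.15)

    def test_positions_inside_spot(self, tirf_model, spot):
        fr = guvforge.render_tirf_frame(50, tirf_model, spot, 2)
        assert fr.positions.shape == (50, 2)
        assert np.all(spot.contains(fr.positions[:, 0], fr.positions[:, 1]))

    def test_signal_linear_in_molecule_count(self, tirf_model, spot):
        per_mol = tirf_model.photons_per_molecule * tirf_model.em_gain
        for n in (100, 400):
            fr = guvforge.render_tirf_frame(n, tirf_model, spot, 3)
            total = (fr.image.astype(float) - tirf_model.baseline).sum()
            assert total == pytest.approx(n * per_mol, rel=0.05)

    def test_dense_binned_rendering_conserves_signal(self, tirf_model, spot):
        fr = guvforge.render_tirf_frame(50_000, tirf_model, spot, 4)
        total = (fr.image.astype(float) - tirf_model.baseline).sum() / fr.exposure_scale
        expect = 50_000 * tirf_model.photons_per_molecule * tirf_model.em_gain
        assert total == pytest.approx(expect, rel=0.03)

    def test_exposure_scale_keeps_16bit_range(self, tirf_model, spot):
        fr = guvforge.render_tirf_frame(5_000_000, tirf_model, spot, 5)
        assert fr.exposure_scale < 1.0
        assert fr.image.max() < 65535

    def test_region_outside_frame_rejected(self, tirf_model):
        bad = SpotRegion(cx=10.0, cy=10.0, radius_px=50.0)
        with pytest.raises(ConfigurationError):
            guvforge.render_tirf_frame(10, tirf_model, bad, 6)

    def test_determinism(self, tirf_model, spot):
        a = guvforge.render_tirf_frame(500, tirf_model, spot, 7)
        b = guvforge.render_tirf_frame(500, tirf_model, spot, 7)
        assert np.array_equal(a.image, b.image)
        assert np.array_equal(a.positions, b.positions)


class TestStandardsAndCapture:
    def test_default_levels_span(self):
        stds = guvforge.make_standards()
        levels = sorted({s.molecules_per_chamber for s in stds})
        assert levels[0] == 10.0 and levels[-1] == 1.0e9

    def test_blank_standard(self):
        stds = guvforge.make_standards(levels=[0.0])
        assert len(stds) == 1 and stds[0].molecules_per_chamber == 0.0

    def test_replicate_product(self):
        assert len(guvforge.make_standards(levels=list(np.logspace(1, 9, 9)), replicates=3)) == 27

    def test_negative_level_rejected(self):
        with pytest.raises(ConfigurationError):
            guvforge.make_standards(levels=[-5.0])

    def test_capture_response_monotone_with_floor_and_ceiling(self):
        cap = guvforge.CaptureModel()
        xs = np.logspace(0, 10, 50)
        ys = cap.expected_bound(xs)
        assert np.all(np.diff(ys) > 0)
        assert cap.expected_bound(0.0) == cap.n_bkd
        assert ys[-1] < cap.n_sat
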