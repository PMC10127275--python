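"""Pipeline orchestration: configuration, fixture simulation, quantification.

``run_simulate`` writes a complete self-describing fixture directory
(wide-field tiles, per-chamber TIRF frames, calibration-standard frames,
truth tables and a manifest carrying the configuration hash and seed).
``run_quantify`` consumes such a directory — or equivalently structured
real data — and produces per-GUV encapsulation-efficiency records, batch
summaries, the fitted calibration curve and the power-law cross-
calibration report.

All analysis stages are deterministic; every source of randomness lives in
the simulator and is derived from the single ``rng_seed`` through a
``SeedSequence`` spawn tree, so identical configuration and seed reproduce
the fixture bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import calcurve, eequant, guvforge, smcount, vesiseg
from .errors import ConfigurationError, DataError, MissingStandardsError, SaturatedSignalError
from .regions import SpotRegion

__all__ = ["RunConfig", "QuantifyResult", "load_config", "replication_config", "run_simulate", "run_quantify"]


@dataclass(frozen=True)
class RunConfig:
    """Flat configuration for a full simulate/analyze run.

    Units: lengths in um, volumes in pL (chamber volume derived in nL),
    concentrations in molecules per pL, pixel sizes in um/px.
    """

    rng_seed: int
    # population
    n_batches: int = 8
    guvs_per_batch: int = 120
    seed_conc: float = 2.35e6
    volume_median_pl: float = 0.35
    volume_gsd: float = 3.2
    volume_min_pl: float = 0.008
    volume_max_pl: float = 20.0
    ee_family: str = "lognormal"
    ee_mean: float = 0.114
    ee_sd: float = 0.062
    ee_low: float = 0.0
    ee_high: float = 1.0
    ghost_fraction: float = 0.02
    superconc_fraction: float = 0.0
    superconc_factor: float = 4.0
    # capture response of the microarray spot
    capture_n_bkd: float = 26.0
    capture_n_sat: float = 1.0e7
    capture_m: float = 1.0
    capture_c: float = 1.3e7
    capture_a: float = 1.0
    # calibration standards
    standard_level_min: float = 10.0
    standard_level_max: float = 1.0e9
    standard_n_levels: int = 13
    standard_replicates: int = 3
    # chamber geometry (um)
    chamber_width_um: float = 300.0
    chamber_length_um: float = 300.0
    chamber_height_um: float = 32.0
    # TIRF imaging
    tirf_pixel_size_um: float = 0.266
    tirf_psf_sigma_px: float = 1.3
    tirf_photons_per_molecule: float = 600.0
    tirf_em_gain: float = 30.0
    tirf_read_noise_sd: float = 60.0
    tirf_baseline: float = 500.0
    tirf_frame_px: int = 512
    spot_radius_px: float = 180.0
    # wide-field imaging
    wf_pixel_size_um: float = 0.266
    wf_psf_sigma_px: float = 0.8
    wf_photons_per_molecule: float = 8.0
    wf_em_gain: float = 1.0
    wf_read_noise_sd: float = 3.0
    wf_baseline: float = 100.0
    wf_frame_px: int = 512
    guvs_per_tile: int = 12
    # analysis thresholds
    wf_threshold_method: str = "fixed"
    wf_fixed_threshold: float = 25.0
    wf_smoothing_sigma: float = 1.0
    wf_min_circularity: float = 0.5
    detect_min_amplitude: float = 250.0
    detect_local_max_threshold: float = 5.0
    dense_occupancy_threshold: float = 0.10
    # metadata only: lysis mode has no effect on the simulated release
    lysis_mode: str = "optical"

    def __post_init__(self):
        if self.n_batches < 1 or self.guvs_per_batch < 0:
            raise ConfigurationError("n_batches must be >= 1 and guvs_per_batch >= 0")
        if min(self.chamber_width_um, self.chamber_length_um, self.chamber_height_um) <= 0:
            raise ConfigurationError("chamber dimensions must be positive")
        if self.lysis_mode not in ("optical", "chemical"):
            raise ConfigurationError("lysis_mode must be 'optical' or 'chemical'")
        if self.standard_n_levels < 2:
            raise ConfigurationError("standard_n_levels must be >= 2")

    # -- derived quantities -------------------------------------------------

    @property
    def chamber_volume_nl(self) -> float:
        """Assay-chamber volume in nL from the geometric product (um^3 -> nL)."""
        return self.chamber_width_um * self.chamber_length_um * self.chamber_height_um / 1.0e6

    def population_config(self, seed) -> guvforge.PopulationConfig:
        return guvforge.PopulationConfig(
            n_guvs=self.guvs_per_batch,
            volume_median_pl=self.volume_median_pl,
            volume_gsd=self.volume_gsd,
            volume_min_pl=self.volume_min_pl,
            volume_max_pl=self.volume_max_pl,
            seed_conc=self.seed_conc,
            ee_family=self.ee_family,
            ee_mean=self.ee_mean,
            ee_sd=self.ee_sd,
            ee_low=self.ee_low,
            ee_high=self.ee_high,
            ghost_fraction=self.ghost_fraction,
            superconc_fraction=self.superconc_fraction,
            superconc_factor=self.superconc_factor,
            rng_seed=seed,
        )

    def tirf_model(self) -> guvforge.ImagingModel:
        return guvforge.ImagingModel(
            pixel_size=self.tirf_pixel_size_um,
            psf_sigma=self.tirf_psf_sigma_px,
            photons_per_molecule=self.tirf_photons_per_molecule,
            em_gain=self.tirf_em_gain,
            read_noise_sd=self.tirf_read_noise_sd,
            baseline=self.tirf_baseline,
            frame_shape=(self.tirf_frame_px, self.tirf_frame_px),
        )

    def wf_model(self) -> guvforge.ImagingModel:
        return guvforge.ImagingModel(
            pixel_size=self.wf_pixel_size_um,
            psf_sigma=self.wf_psf_sigma_px,
            photons_per_molecule=self.wf_photons_per_molecule,
            em_gain=self.wf_em_gain,
            read_noise_sd=self.wf_read_noise_sd,
            baseline=self.wf_baseline,
            frame_shape=(self.wf_frame_px, self.wf_frame_px),
        )

    def capture_model(self) -> guvforge.CaptureModel:
        return guvforge.CaptureModel(
            n_bkd=self.capture_n_bkd,
            n_sat=self.capture_n_sat,
            m=self.capture_m,
            c=self.capture_c,
            a=self.capture_a,
        )

    def spot_region(self) -> SpotRegion:
        half = (self.tirf_frame_px - 1) / 2.0
        return SpotRegion(cx=half, cy=half, radius_px=self.spot_radius_px)

    def standard_levels(self) -> np.ndarray:
        return np.logspace(
            math.log10(self.standard_level_min),
            math.log10(self.standard_level_max),
            self.standard_n_levels,
        )

    def detect_params(self) -> smcount.DetectParams:
        max_sigma = 2.5 * self.tirf_psf_sigma_px
        return smcount.DetectParams(
            fit_window=2 * math.ceil(3 * max_sigma) + 1,
            min_sigma=0.5 * self.tirf_psf_sigma_px,
            max_sigma=max_sigma,
            min_amplitude=self.detect_min_amplitude,
            local_max_threshold=self.detect_local_max_threshold,
            dense_occupancy_threshold=self.dense_occupancy_threshold,
        )

    def segment_params(self) -> vesiseg.SegmentParams:
        return vesiseg.SegmentParams(
            smoothing_sigma=self.wf_smoothing_sigma,
            threshold_method=self.wf_threshold_method,
            fixed_threshold=self.wf_fixed_threshold,
            min_radius=2.0,
            max_radius=0.45 * self.wf_frame_px,
            min_circularity=self.wf_min_circularity,
        )

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        if "rng_seed" not in data:
            raise ConfigurationError("rng_seed is mandatory")
        coerced = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        for key, value in data.items():
            # YAML 1.1 reads exponents without a sign ("1e7") as strings
            try:
                if types[key] == "float":
                    value = float(value)
                elif types[key] == "int":
                    value = int(value)
            except (TypeError, ValueError) as exc:
                raise ConfigurationError(f"config key {key}: {exc}") from exc
            coerced[key] = value
        return cls(**coerced)


def load_config(path, **overrides) -> RunConfig:
    """Load a flat YAML config file; keyword overrides win over file values."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigurationError("config file must contain a flat mapping")
    data.update(overrides)
    return RunConfig.from_dict(data)


def replication_config(**overrides) -> RunConfig:
    """The shipped batch-replication configuration (8 batches x 120 GUVs)."""
    from importlib import resources

    path = resources.files("guvquant") / "configs" / "replication.yaml"
    with resources.as_file(path) as p:
        return load_config(p, **overrides)


# ---------------------------------------------------------------------------
# simulation stage
# ---------------------------------------------------------------------------


def _prepare_out_dir(out_dir, force: bool) -> Path:
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise ConfigurationError(f"output directory {out} exists and is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)
    return out


def run_simulate(config: RunConfig, out_dir, *, force: bool = False) -> Path:
    """Simulate a complete fixture: images, truth tables and manifest.

    Layout::

        truth.csv                    per-GUV ground truth (simulation only)
        placements.csv               operator stage log: tile + position per GUV
        widefield/b##_t##.tif        wide-field tiles
        tirf/chambers.csv            chamber map (spot geometry, exposure)
        tirf/b##_c####.tif           per-chamber TIRF frames
        standards/standards.csv      calibration series (level, replicate)
        standards/s###.tif           standard frames
        manifest.json                config, hash, seed, derived chamber volume
    """
    out = _prepare_out_dir(out_dir, force)
    (out / "widefield").mkdir(exist_ok=True)
    (out / "tirf").mkdir(exist_ok=True)
    (out / "standards").mkdir(exist_ok=True)

    ss = np.random.SeedSequence(config.rng_seed)
    batch_seeds = ss.spawn(config.n_batches)
    standards_seed = ss.spawn(1)[0]

    wf_model = config.wf_model()
    tirf_model = config.tirf_model()
    capture = config.capture_model()
    region = config.spot_region()

    truth_rows, placement_rows, chamber_rows = [], [], []
    chamber_idx = 0
    for b, bseed in enumerate(batch_seeds):
        pop_seed, place_seed, capture_seed, frame_seed_root = bseed.spawn(4)
        pop = guvforge.sample_population(
            config.population_config(pop_seed.generate_state(1)[0] % (2**31))
        )
        # global ids across batches
        pop = [dataclasses.replace(g, id=b * config.guvs_per_batch + g.id) for g in pop]

        # deal vesicles into tiles largest-first, round-robin, to balance area
        n_tiles = max(1, math.ceil(len(pop) / config.guvs_per_tile))
        order = np.argsort([-g.radius_um for g in pop])
        tiles: list[list[guvforge.GUVTruth]] = [[] for _ in range(n_tiles)]
        for j, idx in enumerate(order):
            tiles[j % n_tiles].append(pop[idx])
        place_children = place_seed.spawn(n_tiles)
        for t, (members, pseed) in enumerate(zip(tiles, place_children)):
            scene = guvforge.render_widefield(members, wf_model, pseed)
            tile_name = f"b{b:02d}_t{t:02d}.tif"
            tifffile.imwrite(out / "widefield" / tile_name, scene.image)
            for g, (x, y) in zip(members, scene.positions):
                placement_rows.append(
                    dict(batch=b, tile=tile_name, guv_id=g.id, x_px=round(float(x), 3), y_px=round(float(y), 3))
                )
                truth_rows.append(
                    dict(
                        guv_id=g.id,
                        batch=b,
                        radius_um=g.radius_um,
                        volume_pL=g.volume_pl,
                        true_ee=g.true_ee,
                        true_copies=g.true_copies,
                        klass=g.klass,
                        tile=tile_name,
                        x_px=round(float(x), 3),
                        y_px=round(float(y), 3),
                    )
                )

        # chambers: one trapped-and-lysed GUV per chamber; ghosts are not
        # visible under fluorescence and are never trapped
        cap_rng = np.random.default_rng(capture_seed)
        frame_seeds = frame_seed_root.spawn(len(pop))
        for g, fseed in zip(sorted(pop, key=lambda g: g.id), frame_seeds):
            if g.klass == guvforge.GHOST:
                continue
            bound = guvforge.simulate_capture(g.true_copies, capture, cap_rng)
            frame = guvforge.render_tirf_frame(bound, tirf_model, region, fseed)
            frame_name = f"b{b:02d}_c{chamber_idx:04d}.tif"
            tifffile.imwrite(out / "tirf" / frame_name, frame.image)
            chamber_rows.append(
                dict(
                    chamber_id=chamber_idx,
                    batch=b,
                    guv_id=g.id,
                    cx=region.cx,
                    cy=region.cy,
                    radius_px=region.radius_px,
                    exposure_scale=frame.exposure_scale,
                    frame=frame_name,
                )
            )
            chamber_idx += 1

    # calibration standards
    std_rng_seed, std_frame_root = standards_seed.spawn(2)
    std_rng = np.random.default_rng(std_rng_seed)
    standards = guvforge.make_standards(
        levels=config.standard_levels().tolist(), replicates=config.standard_replicates
    )
    std_rows = []
    std_frame_seeds = std_frame_root.spawn(len(standards))
    for i, (std, fseed) in enumerate(zip(standards, std_frame_seeds)):
        bound = guvforge.simulate_capture(std.molecules_per_chamber, capture, std_rng)
        frame = guvforge.render_tirf_frame(bound, tirf_model, region, fseed)
        frame_name = f"s{i:03d}.tif"
        tifffile.imwrite(out / "standards" / frame_name, frame.image)
        std_rows.append(
            dict(
                standard_id=i,
                level=std.molecules_per_chamber,
                replicate=std.replicate_id,
                exposure_scale=frame.exposure_scale,
                frame=frame_name,
            )
        )

    pd.DataFrame(truth_rows).to_csv(out / "truth.csv", index=False)
    pd.DataFrame(placement_rows).to_csv(out / "placements.csv", index=False)
    pd.DataFrame(chamber_rows).to_csv(out / "tirf" / "chambers.csv", index=False)
    pd.DataFrame(std_rows).to_csv(out / "standards" / "standards.csv", index=False)

    manifest = dict(
        config=config.to_dict(),
        config_hash=config.config_hash(),
        rng_seed=config.rng_seed,
        chamber_volume_nl=config.chamber_volume_nl,
        n_chambers=chamber_idx,
        n_standards=len(standards),
    )
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


# ---------------------------------------------------------------------------
# analysis stages
# ---------------------------------------------------------------------------


def _load_frame(path) -> np.ndarray:
    return tifffile.imread(path).astype(float)


def _prepare_spot_frame(img, config: RunConfig, exposure_scale: float) -> np.ndarray:
    """Flatten, remove the camera offset and normalise to unit exposure.

    The offset is the median of the off-spot pixels and is subtracted
    without clipping: dense-mode counting sums ~1e5 pixels, where the
    order-statistic bias of a morphological background estimate (and the
    positive bias of clipping noise at zero) would masquerade as hundreds
    of molecules.  Mean-zero residual noise instead cancels in the sum.
    """
    flat = smcount.flatten_field(img, np.ones_like(img))
    region = config.spot_region()
    yy, xx = np.ogrid[: flat.shape[0], : flat.shape[1]]
    off_spot = (xx - region.cx) ** 2 + (yy - region.cy) ** 2 > (region.radius_px + 20) ** 2
    offset = float(np.median(flat[off_spot]))
    return (flat - offset) / exposure_scale


def count_standards(config: RunConfig, fixture_dir) -> tuple[pd.DataFrame, float]:
    """Count every calibration-standard frame; returns counts and the pooled
    median single-molecule intensity derived from the resolved (sparse)
    standards."""
    fixture = Path(fixture_dir)
    std_csv = fixture / "standards" / "standards.csv"
    if not std_csv.exists():
        raise MissingStandardsError(
            "no calibration standards found; absolute quantification requires them"
        )
    table = pd.read_csv(std_csv)
    params = config.detect_params()
    region = config.spot_region()

    prepared = {}
    resolved: list[tuple[float, int]] = []
    deferred = []
    results = {}
    for row in table.itertuples():
        img = _prepare_spot_frame(
            _load_frame(fixture / "standards" / row.frame), config, row.exposure_scale
        )
        prepared[row.standard_id] = img
        try:
            sc = smcount.count_spot(img, region, params)
        except DataError:
            deferred.append(row.standard_id)
            continue
        if sc.mode == "resolved":
            results[row.standard_id] = sc
            if sc.n_molecules > 0 and sc.mean_sm_intensity > 0:
                resolved.append((sc.mean_sm_intensity, sc.n_molecules))
        else:  # pragma: no cover - count_spot without reference raises instead
            deferred.append(row.standard_id)

    if not resolved:
        raise DataError("no resolved standards to establish the single-molecule intensity")
    pooled = np.repeat([m for m, n in resolved], [n for m, n in resolved])
    mean_sm = float(np.median(pooled))

    for sid in deferred:
        results[sid] = smcount.count_spot(
            prepared[sid], region, params, mean_sm_intensity=mean_sm
        )

    table = table.assign(
        mode=[results[s].mode for s in table.standard_id],
        n_molecules=[results[s].n_molecules for s in table.standard_id],
    )
    return table, mean_sm


def fit_calibration(std_table: pd.DataFrame) -> calcurve.CalibrationCurve:
    standards = [
        guvforge.CalStandard(
            molecules_per_chamber=row.level,
            replicate_id=int(row.replicate),
            observed_count=float(row.n_molecules),
        )
        for row in std_table.itertuples()
        if row.n_molecules > 0
    ]
    return calcurve.fit_fivepl(standards)


def count_chambers(config: RunConfig, fixture_dir, mean_sm: float) -> pd.DataFrame:
    fixture = Path(fixture_dir)
    chambers = pd.read_csv(fixture / "tirf" / "chambers.csv")
    params = config.detect_params()
    rows = []
    for row in chambers.itertuples():
        region = SpotRegion(cx=row.cx, cy=row.cy, radius_px=row.radius_px)
        img = _prepare_spot_frame(
            _load_frame(fixture / "tirf" / row.frame), config, row.exposure_scale
        )
        sc = smcount.count_spot(img, region, params, mean_sm_intensity=mean_sm)
        rows.append(
            dict(
                chamber_id=row.chamber_id,
                batch=row.batch,
                guv_id=row.guv_id,
                mode=sc.mode,
                n_molecules=sc.n_molecules,
                mean_sm_intensity=sc.mean_sm_intensity,
            )
        )
    return pd.DataFrame(rows)


def segment_tiles(config: RunConfig, fixture_dir) -> pd.DataFrame:
    """Segment every wide-field tile and match measurements to the stage log.

    Matching uses only the operator's logged trap positions (tile and
    centre), never the simulation truth.  Unmatched log entries are
    recorded with NaN measurements (e.g. vesicles too dim to segment).
    """
    fixture = Path(fixture_dir)
    placements = pd.read_csv(fixture / "placements.csv")
    params = config.segment_params()
    rows = []
    for tile_name, group in placements.groupby("tile", sort=True):
        img = _load_frame(fixture / "widefield" / tile_name)
        # flat camera offset: robust median (vesicles cover a small fraction)
        sub = img - float(np.median(img))
        seg = vesiseg.segment_vesicles(sub, params, config.wf_pixel_size_um)
        meas = vesiseg.measure_vesicles(
            seg, sub, config.wf_pixel_size_um, psf_sigma=config.wf_psf_sigma_px
        )
        available = list(meas)
        for row in group.itertuples():
            best, best_d = None, np.inf
            for m in available:
                d = math.hypot(m.centroid[0] - row.x_px, m.centroid[1] - row.y_px)
                if d < best_d:
                    best, best_d = m, d
            tol = 4.0
            if best is not None:
                tol = max(4.0, 0.5 * best.radius_um / config.wf_pixel_size_um)
            if best is not None and best_d <= tol:
                available.remove(best)
                rows.append(
                    dict(
                        guv_id=row.guv_id,
                        batch=row.batch,
                        tile=tile_name,
                        radius_um=best.radius_um,
                        volume_pL=best.volume_pl,
                        total_fluorescence=best.total_fluorescence,
                    )
                )
            else:
                rows.append(
                    dict(
                        guv_id=row.guv_id,
                        batch=row.batch,
                        tile=tile_name,
                        radius_um=np.nan,
                        volume_pL=np.nan,
                        total_fluorescence=np.nan,
                    )
                )
    return pd.DataFrame(rows)


@dataclass
class QuantifyResult:
    records: pd.DataFrame
    pooled: eequant.BatchStats
    per_batch: dict[int, eequant.BatchStats]
    curve: calcurve.CalibrationCurve
    powerlaw: eequant.PowerLawFit | None
    mean_sm_intensity: float
    counts: dict[str, int]


def run_quantify(config: RunConfig, fixture_dir, out_dir, *, force: bool = False) -> QuantifyResult:
    """Run the full analysis chain on a fixture directory.

    Stages: count standards -> fit the 5PL calibration curve -> count every
    chamber and invert to absolute copies -> segment wide-field tiles for
    per-GUV volumes -> per-GUV EE and batch statistics -> power-law
    cross-calibration report.  Raises if standards are missing (absolute
    quantification is impossible from arbitrary units alone) or if required
    inputs are absent.
    """
    fixture = Path(fixture_dir)
    if not (fixture / "tirf" / "chambers.csv").exists():
        raise DataError(f"no chamber data found under {fixture}")
    out = _prepare_out_dir(out_dir, force)

    std_table, mean_sm = count_standards(config, fixture)
    curve = fit_calibration(std_table)
    chamber_counts = count_chambers(config, fixture, mean_sm)
    seg_table = segment_tiles(config, fixture)

    merged = chamber_counts.merge(
        seg_table.drop(columns=["batch"]), on="guv_id", how="left", validate="1:1"
    )

    records, flags_count = [], dict(censored=0, saturated=0, unmatched=0, superconc=0, extrapolated=0)
    for row in merged.itertuples():
        flags = []
        if not np.isfinite(row.volume_pL):
            flags_count["unmatched"] += 1
            continue
        try:
            inv = calcurve.invert_fivepl(float(row.n_molecules), curve)
        except SaturatedSignalError:
            flags_count["saturated"] += 1
            records.append(
                dict(
                    guv_id=row.guv_id, batch=row.batch, volume_pL=row.volume_pL,
                    total_fluorescence=row.total_fluorescence, measured_copies=np.nan,
                    expected_copies=eequant.expected_copies(row.volume_pL, config.seed_conc),
                    ee_percent=np.nan, flags="saturated",
                )
            )
            continue
        expected = eequant.expected_copies(row.volume_pL, config.seed_conc)
        if inv.censored:
            flags_count["censored"] += 1
            flags.append("censored")
            measured, ee = np.nan, np.nan
        else:
            if inv.extrapolated:
                flags_count["extrapolated"] += 1
                flags.append("extrapolated")
            measured = inv.molecules
            ee = eequant.ee_percent(measured, expected)
            if ee > 100.0:
                flags_count["superconc"] += 1
                flags.append("superconc")
        records.append(
            dict(
                guv_id=row.guv_id, batch=row.batch, volume_pL=row.volume_pL,
                total_fluorescence=row.total_fluorescence, measured_copies=measured,
                expected_copies=expected, ee_percent=ee, flags="|".join(flags),
            )
        )
    rec = pd.DataFrame(records)
    if rec.empty or not np.isfinite(rec.ee_percent).any():
        raise DataError("no quantifiable GUVs: nothing matched or everything censored")

    ok = rec[np.isfinite(rec.ee_percent)]
    pooled = eequant.batch_stats(ok.ee_percent)
    per_batch = {
        int(b): eequant.batch_stats(grp.ee_percent) for b, grp in ok.groupby("batch")
    }

    powerlaw = None
    good = ok[(ok.total_fluorescence > 0) & (ok.measured_copies > 0)]
    if len(good) >= 3:
        powerlaw = eequant.fit_shared_powerlaw(
            micro=good[["volume_pL", "total_fluorescence"]].to_numpy(),
            sm=good[["volume_pL", "measured_copies"]].to_numpy(),
        )

    # ---- outputs -----------------------------------------------------------
    rec.to_csv(out / "ee_records.csv", index=False)
    std_table.to_csv(out / "standard_counts.csv", index=False)
    chamber_counts.to_csv(out / "chamber_counts.csv", index=False)
    (out / "calibration_curve.txt").write_text(curve.to_text())
    summary_rows = []
    for label, st in [("pooled", pooled)] + [(str(b), s) for b, s in sorted(per_batch.items())]:
        summary_rows.append(
            dict(
                batch=label, n=st.n, mean=st.mean, sd=st.sd, median=st.median,
                q1=st.q1, q3=st.q3, whisker_low=st.whisker_low, whisker_high=st.whisker_high,
                n_outliers=len(st.outliers), span_orders=st.span_orders,
            )
        )
    pd.DataFrame(summary_rows).to_csv(out / "batch_summary.csv", index=False)
    if powerlaw is not None:
        (out / "powerlaw_fit.txt").write_text(
            f"a_mu: {powerlaw.a_mu!r}\na_sm: {powerlaw.a_sm!r}\nk: {powerlaw.k!r}\n"
            f"scale_ratio: {powerlaw.scale_ratio!r}\nfit_rms: {powerlaw.fit_rms!r}\n"
            f"k_micro: {powerlaw.k_micro!r}\nk_sm: {powerlaw.k_sm!r}\n"
        )
    log = dict(
        config_hash=config.config_hash(),
        rng_seed=config.rng_seed,
        mean_sm_intensity=mean_sm,
        detect_params=dataclasses.asdict(config.detect_params()),
        segment_params=dataclasses.asdict(config.segment_params()),
        flags=flags_count,
        n_records=int(len(rec)),
        n_quantified=int(len(ok)),
    )
    (out / "run_log.json").write_text(json.dumps(log, indent=2, sort_keys=True))

    return QuantifyResult(
        records=rec,
        pooled=pooled,
        per_batch=per_batch,
        curve=curve,
        powerlaw=powerlaw,
        mean_sm_intensity=mean_sm,
        counts=flags_count,
    )
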