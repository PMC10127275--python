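# Batch-replication configuration: 8 independently seeded batches of 120
# GUVs each, analysed end to end.  The true-EE distribution is a truncated
# log-normal with arithmetic mean 11.4% and SD 6.2% (fractions below), the
# right-skewed shape spanning somewhat over a decade that phase-transfer
# GUV preparations show.  Seed-solution concentration is 2.35e6 molecules
# per pL.  All values are in the units documented in RunConfig.
rng_seed: 20230328

n_batches: 8
guvs_per_batch: 120
seed_conc: 2.35e+06

# analysed-vesicle volume distribution (pL): log-normal, truncated
volume_median_pl: 0.35
volume_gsd: 3.2
volume_min_pl: 0.008
volume_max_pl: 20.0

# true encapsulation efficiency (fractions)
ee_family: lognormal
ee_mean: 0.114
ee_sd: 0.062
ee_low: 0.0
ee_high: 1.0
ghost_fraction: 0.02
superconc_fraction: 0.0
superconc_factor: 4.0

# saturable capture response of the microarray spot (molecules)
capture_n_bkd: 26.0
capture_n_sat: 1.0e+07
capture_m: 1.0
capture_c: 1.3e+07
capture_a: 1.0

# calibration standards: log-spaced molecules per chamber
standard_level_min: 10.0
standard_level_max: 1.0e+09
standard_n_levels: 13
standard_replicates: 3

# assay-chamber geometry (um)
chamber_width_um: 300.0
chamber_length_um: 300.0
chamber_height_um: 32.0

# TIRF acquisition
tirf_pixel_size_um: 0.266
tirf_psf_sigma_px: 1.3
tirf_photons_per_molecule: 600.0
tirf_em_gain: 30.0
tirf_read_noise_sd: 60.0
tirf_baseline: 500.0
tirf_frame_px: 512
spot_radius_px: 180.0

# wide-field acquisition
wf_pixel_size_um: 0.266
wf_psf_sigma_px: 0.8
wf_photons_per_molecule: 8.0
wf_em_gain: 1.0
wf_read_noise_sd: 3.0
wf_baseline: 100.0
wf_frame_px: 512
guvs_per_tile: 12

# analysis thresholds
wf_threshold_method: fixed
wf_fixed_threshold: 25.0
wf_smoothing_sigma: 1.0
wf_min_circularity: 0.5
detect_min_amplitude: 250.0
detect_local_max_threshold: 5.0
dense_occupancy_threshold: 0.10

lysis_mode: optical
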