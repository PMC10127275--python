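# guvquant

Absolute quantification of protein encapsulation in giant unilamellar
vesicles (GUVs), with a full synthetic-data generator so the entire
pipeline is testable against ground truth.

GUVs are cell-sized lipid compartments used as artificial-cell chassis.
A persistent, mostly unspoken assumption is that a vesicle's interior has
the composition of the seed solution it was formed from. Measuring how
true that is requires *absolute* per-vesicle copy numbers, which bulk
fluorescence cannot provide. This package implements the analysis chain
of a microfluidic single-molecule microarray assay that can: vesicles are
sized by wide-field fluorescence microscopy, individually lysed in
nanolitre chambers, and their released protein is counted molecule by
molecule on a capture spot imaged by TIRF microscopy. It is written for
researchers building or auditing vesicle-based artificial cells, and for
anyone who wants a reference implementation of single-molecule spot
counting with a dense-regime fallback, five-parameter logistic (5PL)
immunoassay calibration, and projection-aware vesicle photometry.

## The quantities it computes

Per vesicle of volume `V` (pL) from a seed solution of concentration
`C` (molecules/pL), the encapsulation efficiency is

    EE (%) = 100 · N_measured / (C · V)

`N_measured` comes from the single-molecule count `N_SM` on the capture
spot through the 5PL standard curve

    N_SM(x) = N_bkd + (N_sat − N_bkd) / (1 + (c/x)^m)^A

fitted to standards spanning 10–1e9 molecules per chamber and inverted in
closed form; counts at the background asymptote are censored at the limit
of detection rather than reported as zero. Microscopy intensities are
cross-calibrated to absolute units through the shared-exponent power laws
`I = a_µ V^k`, `N = a_SM V^k`, whose quotient `a_SM/a_µ` is a
volume-independent scale factor. Batches are summarised with Tukey
box-whisker statistics (whiskers at the most extreme values within
1.5 IQR of the quartiles).

Modules: `guvforge` (synthetic populations, wide-field and TIRF
renderers, calibration standards), `smcount` (2D-Gaussian single-molecule
detection and resolved/dense spot counting), `calcurve` (5PL fit and
inversion), `vesiseg` (GUV segmentation and projection-corrected
radius/volume measurement), `eequant` (power-law cross-calibration, EE,
batch statistics), `pipeline` (configuration, fixture simulation, the
full analysis chain) and a `guvquant` command-line tool.

## Worked example

Simulate the shipped replication study (8 batches × 120 GUVs, seed
concentration 2.35e6 molecules/pL, truncated log-normal true EE) and
analyse it end to end:

```sh
guvquant simulate --seed 11 --out fixture
guvquant quantify --fixture fixture --out analysis
guvquant report --results analysis
```

which prints (seed 11):

```
quantified 945 GUVs: mean EE 11.5% (SD 6.0%), median 10.1%, span 1.37 orders
 batch   n      mean       sd    median       q1        q3  whisker_low  whisker_high  n_outliers  span_orders
pooled 945 11.491284 5.996162 10.096134 7.385491 14.360024     1.836868     24.626103          41     1.367180
     0 119 10.626283 4.816276  9.645371 7.298762 13.351915     3.016978     20.030206           3     0.999664
     1 118 11.377172 5.849914  9.856545 7.317000 14.376622     3.169136     22.900708           6     1.004044
```

Reading this: of 960 simulated vesicles, 945 were segmented, counted and
quantified (ghosts are invisible to fluorescence segmentation and are
reported separately). The pooled per-GUV encapsulation efficiency is
11.5% ± 6.0% — i.e. vesicles on average capture about a ninth of the
seed-solution concentration, with large vesicle-to-vesicle spread: the
population spans ~1.4 orders of magnitude, and 41 vesicles lie beyond the
Tukey whiskers. Per-batch rows show the batch-to-batch consistency of the
mean around ~10–12%. The run directory also contains the per-GUV records
(`ee_records.csv`), the fitted calibration curve
(`calibration_curve.txt`), the shared-exponent power-law fit
(`powerlaw_fit.txt`) and a provenance log with every threshold and seed
(`run_log.json`).

The same chain is available as a library:

```python
import guvquant as gq

cfg = gq.replication_config(rng_seed=11)
fixture = gq.run_simulate(cfg, "fixture")
result = gq.run_quantify(cfg, fixture, "analysis")
print(result.pooled.mean, result.pooled.sd)
```

`docs/methods.md` describes the underlying models — the chord-projection
vesicle renderer, the EMCCD noise model, the saturable capture response,
the projection-corrected radius estimator — and every tunable parameter.

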