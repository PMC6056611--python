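# neopli

Phase lag index (PLI) functional connectivity and maturation statistics for
neonatal multichannel EEG.

In neonates, the organisation of functional brain networks changes rapidly
with postmenstrual age (PMA): as regions differentiate and myelination
proceeds, globally consistent phase coupling between scalp electrodes
weakens.  `neopli` implements the sensor-space analysis that quantifies
this: it computes the phase lag index between all pairs of the 21-electrode
10–20 montage, aggregates it to whole-head means per frequency band, and
relates those means to PMA across a cohort with an outlier-gated
correlation/regression battery.  Because clinical neonatal EEG cohorts are
rarely shareable, the package ships a synthetic cohort generator with a
known maturation trend, so the entire pipeline can be exercised, tested and
calibrated end to end.

Intended users: researchers in neonatal electrophysiology and developers of
EEG maturation biomarkers who need a tested, reproducible PLI pipeline.

## The statistic

For two channels with instantaneous phases φ_a(t_k), φ_b(t_k) (analytic
signal of the band-filtered epoch), the phase lag index is

    PLI = | ⟨ sign( sin(Δφ(t_k)) ) ⟩ |,   Δφ = φ_a − φ_b,

the absolute time average of the sign of the sine of the phase difference,
with sign(0) = 0.  PLI is 0 when there is no consistent lead/lag (in
particular for the zero-lag coupling produced by volume conduction, which
it discards by construction) and 1 for a perfectly consistent nonzero lag.

Aggregation conventions:

* **mPLI** — mean PLI over all 210 channel pairs per epoch, then over the
  first 50 epochs (4096 samples at 250 Hz each), per subject and band;
* **pwPLI** — per-pair PLI averaged over epochs: a symmetric 21×21
  connectivity matrix per subject.

The cohort battery correlates mPLI with PMA per band (Pearson, or Spearman
for bands whose mPLI distribution contains |z| > 3.29 outliers), fits
mPLI = B0 + B1·PMA by ordinary least squares, tests gestational age and
birth weight as hierarchical covariates (R² change F tests), contrasts
groups with Mann–Whitney U, and maps the per-pair correlation topography
(significance at p < 1e-4; global analyses at p < 0.005).

## Worked example

```python
from neopli import GeneratorConfig, RunConfig, simulate_cohort, run_cohort

cohort = simulate_cohort(GeneratorConfig(seed=1))     # 131 subjects
report = run_cohort(cohort.iter_subjects(),
                    RunConfig(bands=("delta",), run_topography=False))

corr = report.band_correlations["delta"]
reg = report.regression
print(f"delta r = {corr.coefficient:.3f} (p = {corr.p_value:.1e}, "
      f"{corr.method}, n = {corr.n})")
print(f"mPLI = {reg.intercept_b0:.3f} {reg.slope_b1:+.5f} * PMA, "
      f"R^2 = {reg.r_squared:.3f}")
```

prints (about three minutes of compute; signals are generated on the fly):

```
delta r = -0.632 (p = 5.4e-16, pearson, n = 131)
mPLI = 0.343 -0.00493 * PMA, R^2 = 0.400
```

That is: on the default synthetic cohort — 131 subjects with PMA uniform on
27.6–45.3 weeks whose delta-band (0.5–4 Hz) coupling follows the line
0.344 − 0.005·PMA plus individual dispersion — the full pipeline recovers a
strongly negative delta mPLI–PMA correlation and the generating line's
coefficients, with PMA explaining ~40 % of the between-subject variance.

A command-line interface mirrors the library
(`neopli simulate | preprocess | connectivity | stats | run-all`); see
`neopli --help`.

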