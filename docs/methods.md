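# Methods

This note documents the models, conventions and numerical choices behind
`neopli`, in the order the pipeline runs.

## Montage and pair indexing

The montage is the fixed 21-electrode 10–20 set
Fp2, Fp1, F8, F7, F4, F3, A2, A1, T4, T3, C4, C3, T6, T5, P4, P3, O2, O1,
Fz, Cz, Pz — this exact ordering is the package's canonical convention, and
the A1/A2 ear electrodes are full members of the montage, of the average
reference and of every channel pair.  Unordered pairs are indexed 0..209 in
row-major order of the upper triangle of that ordering; every matrix and
long-format table in the package follows it.  Recordings read from EDF are
re-ordered to this convention by channel label (extra channels dropped, a
missing montage channel is fatal); text matrices are assumed to already be
in it.  Amplitudes are microvolts, ages decimal weeks
(40 weeks + 1 day = 40.142857).

EDF reading goes through `mne`; EDF writing is a small 16-bit writer
implemented here (round trips are verified against the `mne` reader in the
test suite).  Quantisation error is bounded by the per-channel physical
range divided by 65535.

## Preprocessing

Order of operations: **average reference → decimate → segment → band-pass**.
Referencing and decimation are linear and commute; segmentation precedes
filtering so each epoch is an independent analysis unit.  Conventions:

* Average reference subtracts the instantaneous mean over all 21 channels
  (idempotent; channel mean is 0 at every sample afterwards).
* Decimation 500 → 250 Hz keeps every second sample.  This assumes the
  acquisition chain low-passed the signal at 100 Hz, well below the 125 Hz
  target Nyquist; an optional zero-phase anti-alias low-pass is available
  for inputs of unknown provenance (`antialias=True`).
* Segmentation takes the first 50 consecutive, non-overlapping epochs of
  4096 samples (16.384 s) from the start of the recording; epoch k spans
  samples [k·4096, (k+1)·4096).  Shorter recordings are fatal unless
  `allow_short` is set, in which case the epoch count actually used is
  recorded in the output.
* Band-pass filtering is zero-phase by construction: per epoch, a real FFT,
  a real-valued spectral mask, and the inverse transform.  The mask is 1 in
  the passband with raised-cosine transitions of width max(0.2 Hz, 5 % of
  the edge frequency) centred on each band edge, so masks of adjacent
  canonical bands cross at amplitude 0.5 exactly on the shared edge.  A
  real mask cannot alter phase relations — a precondition for a phase-based
  connectivity statistic.  The canonical band table is broad 0.1–45, delta
  0.5–4, theta 4–8, lower alpha 8–10, upper alpha 10–13, beta 13–30, gamma
  30–45 Hz.
* The acquisition high-pass (amplifier time constant τ, cutoff 1/(2πτ);
  0.265 Hz for τ = 0.6 s) is a property of the input data.  The pipeline
  documents it (`highpass_cutoff`) but never re-applies it.

## Phase lag index

Phases are the analytic-signal (Hilbert) phases of each band-filtered
epoch, computed per epoch with no padding and no edge trimming; an
identically zero channel gets phase 0 and a flag.  The pair statistic is
|mean sign(sin Δφ)| with sign(0) = 0 exactly: phase differences at 0 mod π
dilute the average rather than counting for either direction, which is what
makes the statistic blind to instantaneous (volume-conducted) coupling.
sin(Δφ) is treated as zero only when it is exactly zero in floating
arithmetic — no epsilon band.  A practical consequence: two channels that
are the same signal scaled by a power of two give PLI exactly 0 (the
transform scales exactly), whereas an arbitrary gain leaves rounding-level
phase jitter whose random signs land the PLI at or below the chance level
~sqrt(2/(πN)) instead of exactly 0.  Both behaviours are asserted in the
tests.

The chance level sqrt(2/(πN)) is the half-normal mean of |an average of N
i.i.d. ±1 signs|.  It describes i.i.d. phase differences.  The analytic
signal of band-limited noise is temporally autocorrelated (even for white
input, the one-sided spectrum induces |r(1)| = 2/π), so the empirical null
of the full filter→Hilbert→PLI path sits above this closed form — around
0.116 for delta-filtered noise at 4096-sample epochs.  The synthetic-cohort
calibration (below) absorbs this floor; the closed form is verified against
its own i.i.d. construction.

Aggregation: per-epoch matrices are averaged entrywise over epochs (pwPLI),
and the scalar mPLI is the mean over the 210 upper-triangle pairs and then
over epochs; the two means commute exactly.

## Spectral summary

Per-epoch rectangular-window periodograms, scaled so bin powers sum to the
time-domain mean square (Parseval).  Relative band power pools power over
all 21 channels before forming the ratio against the broad band
(0.1–45 Hz); bins belong to a band by low ≤ f < high, so adjacent canonical
bands never double-count a shared edge.  Per-channel-then-average was the
other defensible convention; pooled was fixed and documented here.

## Cohort statistics

* All p-values are two-sided.  Global (whole-head) analyses use α = 0.005,
  local (per-pair) analyses α = 1e-4 — fixed thresholds as multiplicity
  control, no formal correction beyond them.
* Outlier gating: a band's mPLI sample is screened for |z| > 3.29 (sample
  sd, n−1).  Pearson is used when no outliers are present, Spearman
  otherwise.  The gate inspects mPLI only, not PMA.
* Regression: OLS of mPLI on PMA with intercept; reported R is signed by
  the slope, so it equals the Pearson correlation (and F = t² — asserted).
* Hierarchical steps: covariates are added cumulatively; each step drops
  subjects missing any of its variables (listwise deletion) and refits both
  nested and augmented models on that step's complete cases, so ΔR² is well
  defined; F_change = ΔR² / ((1−R²_full)/(n−p_full−1)) with 1 numerator df.
  The number of complete cases is always reported.
* Mann–Whitney U with the tie-corrected normal approximation for z (no
  continuity correction) and an exact p for small tie-free samples.
* Topography: Pearson correlation of each pair's pwPLI with PMA, 210
  entries in canonical pair order; ranking from most negative upward with
  ties broken by pair index; zero-variance pairs are recorded as missing
  and excluded from the ranking with a warning.
* Longitudinal trends (≥ 6 time points) report the tie-corrected Spearman ρ
  with an exact permutation p for n ≤ 8 (all n! permutations enumerated;
  a strictly monotone series of 6 points gives p = 2/720), plus the OLS
  line.
* The topography/local band is auto-selected as the band with the strongest
  global association, overridable in the run configuration.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated.  Defaults: 131 subjects, PMA uniform on 27.6–45.3 weeks,
delta-band mPLI following 0.344 − 0.005·PMA with individual dispersion
0.033, 21 channels at 500 Hz, enough signal for 50 epochs of 4096 samples
after 2× decimation.  The dispersion default is derived from the targeted
correlation strength: with PMA uniform over 17.7 weeks and slope
−0.005/week, a residual sd of 0.033 makes the line's Pearson correlation
come out near −0.62.

Signal model per subject:

* **Background noise**: independent per channel, built in the frequency
  domain as Gaussian noise shaped to 1/f^2.5 with a two-pole low-frequency
  rolloff at 0.7 Hz and a 100 Hz acquisition-style low-pass.  This gives a
  delta-dominant spectrum (~70 % of broad-band power in 0.5–4 Hz), the
  qualitative signature of neonatal EEG.
* **Coupling**: one shared narrow-band oscillator in the coupling band
  (delta by default), mixed into every channel with amplitude κ and
  per-channel phase offsets.  The offsets are cumulative increments, each
  drawn from (π/8, 3π/8): every adjacent lag is guaranteed nonzero (hence
  PLI-visible) while the offsets spread around the circle.  The spreading
  matters: offsets drawn i.i.d. from one narrow arc have, after the common
  average is subtracted, residual mixing coefficients that are real
  multiples of a single complex direction — pairwise lags of exactly 0 or π
  to first order, which a phase-lag statistic discards.  The cumulative
  construction survives re-referencing.  When designated pairs are planted
  (`coupled_pairs`), each pair gets its own independent oscillator instead,
  so coupling exists only within the designated pairs.
* **Maturation**: PMA enters only through κ.  A Monte-Carlo calibration
  sweep (fixed substream of the config seed) measures the pipeline's
  achieved mPLI over a κ grid, with probe sizes scaled so each sweep point
  has roughly constant Monte-Carlo error, and a monotone interpolant maps a
  requested mPLI to κ.  Requests at or below the noise floor map to κ = 0;
  per-subject targets are clipped to the achievable range (the default line
  reaches the delta floor ≈ 0.116 near PMA 45, exactly as a real cohort's
  mPLI bottoms out at the statistic's chance level).  Achieved-vs-requested
  error is ~0.01–0.02 over the usable range.
* **Metadata** (sex 55 % male, gestational age = PMA minus a lognormal
  postnatal age, birth weight correlated with GA with ~5 % missing,
  diagnosis mix, quality and clinically-normal labels with realistic
  prevalences) are cosmetic marginals for exercising the statistics; they
  are drawn independently of the signal, so label-based subgroups preserve
  the maturation trend by construction.
* **Artifacts**: `inject_artifacts` overlays high-amplitude broadband
  transients on a chosen fraction of chosen epochs and derives a quality
  label mechanically: among probe epochs 1, 10, 20, 30, 40, 50, an epoch
  counts as artifacted when > 30 % of its samples are affected, and two or
  more such probes give "low" quality.

All randomness flows from one seed: per-subject substreams are derived from
(seed, subject index), longitudinal visits from (seed, subject, visit), and
the calibration sweep from its own fixed substream, so cohorts and results
are bit-identical across runs with the same seed and configuration.

What the generator does **not** model: biophysical neural-mass dynamics,
developmental graphoelements (delta brushes, anterior delta runs), sleep
states, burst/interburst structure, or artifact spectra of real NICU
recordings.  Passing recovery tests therefore shows that the pipeline's
statistics faithfully measure the phase-lag structure the analysis assumes,
not that the generator reproduces clinical EEG.

## Problem sizes used in validation

Full-size runs (cohort recovery, the acceptance script) use the default
conditions: 131 subjects × 50 epochs × 4096 samples, delta band.  The
type-I-error study uses 1000 replicates of reduced cohorts (30 subjects,
3 epochs of 512 samples, flat maturation line), and the planted-topography
recovery uses 40 subjects × 10 epochs with three designated pairs; reduced
sizes raise the PLI noise floor (to ~0.30 at 3×512), so reduced-size
configurations place their target lines accordingly.  Unit tests run on
yet smaller fixtures.

## Known limitations

* The exact-zero signum convention makes PLI of numerically identical
  signals exactly 0 but leaves rounding-level jitter at chance level for
  arbitrary-gain copies (documented above).
* The EDF writer covers the plain 16-bit EDF variant only (no annotations,
  no EDF+ discontinuous records).
* The Mann–Whitney z uses the asymptotic tie-corrected approximation; exact
  enumeration applies only to the p-value of small tie-free samples.
* No mixed-effects modelling of repeated measures: longitudinal subjects
  are analysed descriptively (rank correlation + per-subject OLS).
* Relative band power pools channels before forming ratios; per-channel
  variants would differ for strongly heterogeneous topographies.
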