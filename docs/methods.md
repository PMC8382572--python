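# Methods

This note records the scientific and numerical choices behind `brainvitals`:
what the simulator emulates, how the extraction pipeline is parameterized,
how the statistics are defined, and where the genuinely open design choices
were settled.

## The measurement framework

A participant-session is summarized by six numbers: amplitude (µV) and
latency (ms) of the N100, P300 and N400 event-related potentials. The N100
and P300 are read from the average response to rare deviant tones in an
oddball stream (the deviant response carries both the sensory N100 and the
attention-driven P300); the N400 is read from the incongruent-minus-congruent
difference wave of word-pair responses, the standard convention for isolating
the semantic-incongruity effect. Amplitudes are reported as magnitudes, with
polarity handled by the detector (the N100 and N400 are negative-going), so
that all six measures are positive numbers as they appear in normative
tables.

## Forward model

Each ERP component is a Gaussian-windowed deflection with peak magnitude,
center latency and FWHM width (defaults 30 ms for N100, 80 ms for P300,
100 ms for N400). Channel topographies are fixed weight maps; the default
measurement electrode of each component (Cz for N100 and N400, Pz for P300)
carries weight 1.0 so that ground truth is identifiable at the electrode the
pipeline reads. Deviant tones contribute N100 + P300; incongruent word
targets contribute the N400; standards and congruent targets contribute
nothing, making the standard-tone average a signal-free reference and the
difference wave the N400 carrier.

**Amplitude calibration.** Ground-truth amplitudes are defined at the
pipeline's analysis point: after the 0.5–20 Hz zero-phase band-pass and
baseline correction. A narrow deflection loses part of its peak to the 20 Hz
edge, and the sharp 0.5 Hz high-pass places a long undershoot around every
deflection that leaks under the peaks of same-event neighbors (the P300's
undershoot sits beneath the N100 and vice versa). Because the whole chain is
linear, the injected template amplitudes are obtained by solving a small
linear system: the "measurement matrix" maps unit templates at the
component latencies through filter + baseline correction and reads the
values at those latencies; its inverse applied to the target amplitudes
yields the template scaling. A noiseless recording therefore round-trips
with zero latency error (templates are snapped to the 2 ms sample grid) and
amplitude error well below 1%.

**Noise model.** Background noise per channel is independent
1/f-shaped + white noise (default 8 µV total SD, 60% of variance pink) — a
realistic magnitude for gel-electrode EEG restricted to the 0.5–20 Hz band.
Blinks are biphasic ~400 ms transients on the EOG channel at a Poisson rate
(default 0.1 Hz, 150 µV) propagating onto Fz/Cz/Pz with fixed coefficients
(0.35/0.2/0.1). What the model deliberately omits: spatially correlated
background across channels, rhythmic alpha, trial-to-trial component
variability (amplitude/latency jitter within a session), muscle and movement
artifacts, and drift nonstationarity. Passing recovery tests therefore
demonstrate correctness of the pipeline's arithmetic and its robustness to
stationary colored noise and blinks — not performance on every artifact type
real recordings contain.

**Protocol sizes.** Exact stimulus counts and timings are configuration, not
contract. The default session emulates a compressed ~6-minute assessment:
300 tones at 0.6 s ISI (60 deviants, 20%, pseudorandomized with no two
deviants adjacent) followed by 70 word pairs (prime–target onset asynchrony
1.0 s, pair every 2.5 s). Waveform-recovery validation uses a larger
recovery-study size (600 tones / 120 word pairs per session) so that
averaging noise, not trial-count starvation, limits accuracy.

**Cohort emulation.** The default two-arm study: arm A, 58 male adolescents
(age 16.24 ± 0.76), scanned twice two days apart with 46 retested, 6
excluded for quality at session 1, and 15 non-fluent participants whose N400
is not measured; arm B, 135 mixed-sex participants aged 8–83
(40.62 ± 16.88), scanned once, one participant without a measurable N100.
Per-measure population means/SDs are the arms' published-style normative
values; between-session draws are bivariate normal with per-measure retest
correlations (0.5–0.7), and session-2 N400 amplitude is multiplied by a
habituation factor of 0.815 (short-interval repeat testing reduces the
N400). Linear age slopes (+0.02 µV/y N100 amp, +0.01 ms/y N100 lat,
−0.05 µV/y P300 amp, +0.20 ms/y P300 lat, −0.046 µV/y N400 amp, +0.28 ms/y
N400 lat) encode the dominant lifespan trends — amplitude decline in P300
and N400 — with the residual SD reduced so the configured total SD is
preserved. These values were fixed once from the emulated study's reported
moments and effect directions and are not tuned thereafter. Latency draws
are snapped to the 2 ms grid of a 500 Hz clock; amplitudes are truncated at
a small positive floor since they are magnitudes.

## Extraction pipeline

Order of operations: band-pass → ocular correction → epoching with baseline
correction → per-epoch wavelet shrinkage → rejection → QC → averaging →
peak measurement.

- **Band-pass**: 4th-order Butterworth (0.5–20 Hz) applied forward-backward
  (`sosfiltfilt`), i.e. zero-phase with 8th-order magnitude. A gentler
  high-pass slope was evaluated and rejected: a 1st-order 0.5 Hz high-pass
  attenuates 30–100 ms deflections by 12–17% because of its broad rolloff,
  whereas the sharp edge preserves the passband and its transient undershoot
  is handled by the amplitude calibration above.
- **Ocular correction**: normalized least-mean-squares (NLMS) adaptive
  filter, each scalp channel predicted from the last 3 EOG samples. Step
  size 0.002: large steps make the stochastic gradient partially cancel the
  ERP itself (measured ~10% amplitude leakage at step 0.01, ~2% at 0.002),
  while convergence on constant blink-propagation coefficients needs only a
  few seconds of data. Residual scalp–EOG correlation after correction stays
  below 0.05 in simulations with known propagation.
- **Epoching**: window −100…+900 ms, baseline −100…0 ms (covers the N400
  window with a conventional pre-stimulus baseline). Epochs overlapping
  recording edges are dropped and counted. Baseline correction is re-applied
  after denoising so the baseline-mean invariant holds exactly.
- **Wavelet shrinkage**: per-channel sym4 decomposition (≤5 levels), soft
  universal threshold with the noise scale from the finest-level MAD,
  applied only to detail levels finer than 16 ms. Coarser levels carry the
  ERP morphology; thresholding them biases peak amplitudes downward in
  proportion to noise. For band-limited noise the finest levels are nearly
  empty and the step is close to a no-op — it matters for broadband
  artifacts that survive the analog band.
- **Rejection / QC**: an epoch is rejected iff any scalp-channel sample
  exceeds ±75 µV (EOG excursions alone never reject). A participant-session
  is excluded for quality iff the rejected fraction is strictly greater than
  25% — the boundary case of exactly 25% is retained.
- **Peak measurement**: within fixed component windows (N100 70–150 ms, P300
  160–450 ms, N400 280–610 ms — round-number envelopes of the normative
  latency ranges), the detector takes the most extreme interior local
  extremum of the appropriate polarity; ties go to the earliest latency; a
  window with no interior extremum falls back to the window-edge extremum
  and sets a flag. Latency is detected on a Gaussian-smoothed copy of the
  average (kernel SD 8/20/25 ms for N100/P300/N400 — roughly a quarter of
  each component's width) to stop residual noise from relocating broad
  peaks, and the amplitude is then read from the *unsmoothed* average at the
  detected sample, which avoids both the extreme-value bias of a raw argmax
  under noise and the attenuation bias of reading a smoothed peak.

Accuracy under the default noise at the recovery-study size, as asserted by
the test suite: noiseless sessions reproduce latencies exactly and
amplitudes within 2%; across noisy cohort sessions, the pooled median
absolute latency error is within one sample (2 ms) and the pooled median
relative amplitude error within 10%. Per component, the N100 is the most
precise and the N400 the least: its wide, difference-wave peak makes
single-sample latency precision unattainable at realistic noise, which is
the same reason real N400 test-retest reliability runs lower than N100/P300.

## Standardized scoring

For reference mean µ and SD σ (sample SD, n−1, from the reference arm's
included measurements):

- amplitude: `score = 100 · clip((x − (µ − 3σ)) / 6σ, 0, 1)`
- latency:  `score = 100 · clip(((µ + 3σ) − x) / 6σ, 0, 1)`

The orientation follows the framework's boundary definitions and semantics
— amplitudes above µ+3σ score 100, latencies above µ+3σ score 0, the mean
scores 50 — with the linear map between the boundaries scaled to 0–100.
(Compact printed renderings of this scheme sometimes give the interior
formulas on a 0–1 scale with the two columns transposed; the boundary rows
are unambiguous and fix the orientation implemented here.) The map is
strictly monotone inside the ±3σ band, symmetric about the mean
(score(µ+d) + score(µ−d) = 100), and invariant under common positive
rescaling of x, µ, σ.

## Reliability statistics

All computed from mean squares of the n×2 subjects-by-sessions table,
complete pairs only (listwise deletion):

- **One-way ANOVA** treats the two sessions as independent groups,
  F = MS_between/MS_within on (1, 2n−2) df — the convention used in
  test-retest summary tables; a repeated-measures formulation would be more
  powerful but is not what those tables label.
- **Cronbach's α** with k = 2 items and n−1 variances.
- **ICC(A,1)**: (MS_R − MS_E) / (MS_R + (k−1)MS_E + (k/n)(MS_C − MS_E)).
  The "two-way mixed, single measures, absolute agreement" and two-way
  random absolute-agreement estimators share this arithmetic; the
  mixed/random distinction affects interpretation only. The 95% CI and the
  p-value (F = MS_R/MS_E on (n−1, (n−1)(k−1)) df) follow McGraw & Wong
  (1996). Cross-validated against pingouin to ~1e-10 on random data.

Absolute agreement penalizes constant between-session shifts, which is why
the habituated N400 amplitude shows a depressed ICC even when rank order is
preserved — a property the test suite asserts directly.

## Group comparison

The MANCOVA fits all six measures jointly on intercept + age + group dummy
(reference arm A; differences reported as B−A). Per term, the hypothesis
SSCP for the single-df contrast and the residual SSCP E give Wilks'
Λ = det(E)/det(E+H); Rao's F transformation is exact for single-df terms,
with error df = (n − 3) − 6 + 1. Partial η² = 1 − Λ for these terms.
Listwise-complete cases across all six responses are used for the
multivariate test (the run output records the achieved df); univariate
follow-ups use per-measure complete cases with Type-III F tests and no
multiplicity adjustment by default (a Holm option exists). Estimated
marginal means evaluate the additive model at the covariate grand mean, so
the adjusted difference equals the group coefficient with its t-based SE/CI.
Age regressions are per-group OLS with confidence bands of the regression
mean evaluated at decade-bin midpoints; age is uncentered there since the
predictions are plotted on the natural scale. Cross-validated against
statsmodels MANOVA/OLS to ~1e-8.

Calibration properties asserted by the suite: the group-term type-I error of
the MANCOVA matches its nominal 5% level across 1000 null simulations at
n = 170; EMM confidence intervals achieve ≥93% empirical coverage at the
95% nominal level; ICC estimation recovers a configured ρ = 0.7 within
±0.05 at n = 500.

## Reporting

Descriptives per group/session/measure: n, mean, SD (n−1), median, IQR
(75th−25th percentile, linear-interpolation quantiles), range, min, max.
Radar axes are fixed in the order N100 amp, N100 lat, P300 amp, P300 lat,
N400 amp, N400 lat; profiles are closed polygons on a 0–100 polar axis with
missing axes left as gaps. Every figure's numeric content is also emitted as
CSV, and re-running reporting on identical inputs reproduces those CSVs
byte-for-byte.

## Known limitations

- The forward model's per-session component parameters are fixed (no
  within-session trial-to-trial jitter), so session-level recovery errors
  reflect only measurement noise.
- N400 latency at realistic noise is accurate to roughly ±6 ms, not one
  sample; only the pooled latency accuracy reaches the one-sample level.
- The one-way between-sessions ANOVA understates the power of a paired
  design; it is provided as the conventional summary-table statistic.
- Age effects are modeled linearly; lifespan ERP trends are known to be
  non-linear, and the per-decade binned predictions exist precisely so such
  curvature can be seen when present.
- The simulator's QC/fluency/retest flag emulation reproduces the *counts*
  of the emulated study deterministically; it does not model the mechanisms
  of dropout or signal-quality failure.
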