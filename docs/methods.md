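# Methods

This note documents the generative model, the statistical procedures, the
numerical choices and the known limitations of `icmsmap`.

## Experimental designs

**Amplitude mapping ("experiment 1").** Every stimulable electrode is tested
at eight amplitudes (20, 30, 40, 60, 70, 80, 90, 100 µA) at a fixed 150 Hz.
Electrodes are partitioned into random blocks (default 8 electrodes per
block, one block per session); within a block each (electrode, amplitude)
pair appears exactly three times. Catch trials — full cueing, no current —
are added at round(0.10 × stimulation trials) and placed at uniformly random
positions. The catch count is taken on the stimulation-trial base so it is
computable before interleaving; catch trials are exempt from the ordering
constraint since they deliver no current.

**Ordering constraint.** No two consecutive stimulation trials may use the
same or adjacent electrodes, where adjacency is the 8-neighbourhood
(Chebyshev distance 1) on the 7×7 grid of the same array — the conservative
reading that includes diagonals; sites on different arrays are never
adjacent. Because a single stimulator delivers one train at a time, the
constraint is interpreted as *consecutive*, not simultaneous, trials. The
scheduler is a randomized sequential construction: at each step it picks
uniformly among the eligible electrodes holding the maximum remaining trial
count. Sets of mutually adjacent electrodes behave like a single label (no
two of their trials may ever be consecutive), so whenever such a clique
holds at least half of the remaining trials the next pick is forced into it;
this handles 2×2 electrode blocks, which admit only strictly alternating
schedules. Construction restarts on a dead end (bounded at 10,000) and the
whole partition is re-drawn (bounded at 20) if a block is unschedulable;
everything is deterministic given the seed. A genuinely unschedulable input
(e.g. a single electrode with more than one trial) raises a schedule error.

**Amplitude × frequency mapping ("experiment 2").** Five electrodes — in the
simulator, the responsive electrodes with the highest baseline detection
probability — are tested at 5 amplitudes (20–100 µA) × 6 frequencies
(50–300 Hz). Each triple appears exactly twice per day in pseudorandom order
over three days, i.e. six times in total (30 pooled stimulations per
amplitude–frequency combination across the five electrodes).

**Charge safety.** Charge per phase is amplitude (µA) × phase width (µs) /
1000, in nC; the validator rejects anything above 20 nC. The maximal
protocol stimulus (100 µA, 200 µs) sits exactly at the limit.

## Generative model

The simulator stands in for a participant's per-trial reports. Its defaults
are calibrated once to the summary statistics such a mapping study reports;
they are the package's study conditions, not tuning knobs.

- **Population.** Two 7×7 arrays, 48 connected sites each (one randomly
  chosen site per array is unconnected). Exactly round(0.48 × n) electrodes
  are *responsive* (default 46/96). Responsive electrodes draw a baseline
  detection probability from N(0.52, 0.15²) clipped to [0.05, 0.90].
- **Detection.** P(report) = clip(p_base + 0.002·A, 0, 1) — linear with a
  weak slope, reflecting that responsiveness correlates only weakly with
  amplitude. Defaults put the overall report rate near 0.31 of non-catch
  trials (≈ 381/1229). Catch trials and non-responsive electrodes never
  yield a report, so the catch false-positive rate is exactly 0 by
  construction. The psychometric shape is a stand-in: the studies report no
  per-electrode threshold curves, so a linear-clipped form was chosen for
  transparency, not inferred from data.
- **Modality.** P(proprioceptive | detected) = logistic(−2.6 + 0.02·A), no
  frequency term — amplitude, not frequency, carries the modality effect.
  The defaults give a pooled proprioceptive fraction ≈ 0.21 (≈ 79/381) with
  proprioceptive reports skewed to higher amplitudes.
- **Intensity.** intensity = clip(round(2.0 + 0.02·A + ε), 1, 10) with
  ε ~ N(0, 1.8²). The intercept is the closed-form solution of a mean of
  2.4 a.u. at 20 µA with slope 0.02 (giving 4.0 a.u. at 100 µA). Clipping at
  the scale ends biases the fitted slope slightly low (≈ 0.017–0.018
  recovered) and the 20 µA mean slightly high (≈ 2.6); both stay well within
  the calibration tolerances (±0.01 and ±0.5).
- **Duration.** Categorical over (short, medium, long) with weights
  ∝ (225, 122, 12), independent of amplitude and frequency; a report's
  duration is unrecorded with probability 22/381.
- **Descriptors.** Drawn per modality from a fixed vocabulary (squeeze, tap,
  vibration, blowing, pinch, press, goosebumps → cutaneous; right/forward/
  upward movement → proprioceptive; "other" matches either), with weights
  proportional to the observed shares of total responses and per-modality
  remainders (8.8% cutaneous, 1.3% proprioceptive) pooled as "other". The
  descriptor → modality map is a configuration table and overridable.
- **Receptive fields.** Categorical over six (region, plane) cells. Array-
  level weights put 0.46 on the anterior upper arm for the medial array and
  0.51 on the posterior forearm for the lateral array. Each electrode
  concentrates 70% of its mass on a modal cell drawn from the array weights,
  so pooled response shares are unbiased for the array-level weights while
  individual electrodes are spatially stable.
- **Impedances.** Log-normal (median 50 kΩ, σ = 0.3), identical for
  responsive and non-responsive electrodes, with a small per-session
  log-normal jitter (σ = 0.05) applied to the snapshot taken at the start of
  every session.
- **Randomness.** One master seed spawns named independent streams
  (population, schedule, responses, impedance); the full simulation is
  bit-reproducible for a fixed configuration.

## Statistical procedures

- **Kruskal–Wallis** uses mid-ranks and the standard tie-correction divisor
  1 − Σ(t³−t)/(N³−N); amplitudes and frequencies take a handful of discrete
  values, so the correction is mandatory. p-values come from the χ²
  distribution with k−1 df; results display (k−1, N−k) so both the χ²
  reference df and the residual df are recoverable.
- **Pearson correlation** reports two-sided p via the exact t-transform
  t = r√((n−2)/(1−r²)) on n−2 df, matching conventional software.
- **Two-sample KS** computes D = sup|ECDF₁ − ECDF₂| exactly and the
  asymptotic Kolmogorov p-value at √(mn/(m+n))·D.
- **Dunn–Šidák**: p_adj = 1 − (1−p)^m, computed via expm1/log1p for
  precision, clipped to [0, 1]; monotone in p and bounded by Bonferroni.
- **Gaussian KDE** uses Silverman's rule 0.9·min(sd, IQR/1.34)·n^(−1/5)
  (sd alone when the IQR is zero); a constant sample raises an error with
  guidance rather than a zero bandwidth.
- **Bootstrap of modality composition.** Per iteration (default 10,000), 15
  responses are drawn per amplitude *with replacement* — the standard
  bootstrap, tolerant of pools smaller than 15; a without-replacement mode
  is available behind a flag. Percentages (0–100) of each modality are fitted
  against amplitude (µA) by OLS, so slopes are in percentage points per µA;
  the cutaneous slope distribution is the exact mirror of the proprioceptive
  one because the two percentages sum to 100. Per-amplitude medians of the
  bootstrap percentages and slope KDEs are reported.
- **Trial-history null.** For each amplitude, the empirical P(report |
  previous hit) and P(report | previous miss) pool all sessions, taking each
  trial's predecessor as the preceding non-catch trial of the same session
  (session-initial trials have none and are excluded from conditionals;
  a flag can include catch trials as forced-miss predecessors). The null
  permutes outcomes within (session, amplitude) strata — holding per-stratum
  hit counts fixed, the granularity at which the report distributions are
  estimated — 10,000 times, and reports 5th–95th percentile envelopes using
  order-statistic percentiles (lower/upper), so the bounds are attainable
  values of the discrete shuffle distribution. A companion Kruskal–Wallis
  test compares per-session report proportions across the all / after-hit /
  after-miss conditions at each amplitude, Dunn–Šidák-corrected over
  amplitudes. Conditionals without qualifying predecessors are flagged as
  not computed.

## Pipeline conventions

- Percentiles interpolate linearly between order statistics; modes of
  discrete values take the smallest value among ties.
- "Mostly cutaneous/proprioceptive" for mixed electrodes means a strict
  majority; exact ties are "equal". Electrodes with no detected responses
  are not classified.
- Intensity normalization is min-max per session, (x − min)/(max − min),
  chosen over the literal "subtract the minimum, divide by the maximum"
  (which reaches 1 only when min = 0) as the evident intent of a 0–1 scale;
  the literal variant is available behind a flag. Sessions with constant
  intensity are flagged and excluded from the SD-vs-amplitude correlation,
  which is computed per amplitude on pooled normalized intensities.
- The per-electrode report rate used in the impedance correlation is
  detected/non-catch trials pooled over days.
- Descriptor tables pool descriptors beyond a cumulative 90% coverage into
  an "other" row.

## Problem sizes

The test suite and the acceptance script size their computations as follows:
full default simulations are 2,532 trials (2,304 stimulation + 228 catch),
yielding ≈ 700–760 detected responses; calibration statistics average over
10–50 replicate simulations; bootstrap and permutation procedures run at
their default N = 10,000; oracle-equivalence checks use 1,000 random small
instances; Kruskal–Wallis type-I error uses 5,000 null simulations; the
trial-history calibration uses 100 simulated three-session datasets.

## Known limitations

- The simulator shares one modality curve (β₀, β₁) across electrodes, so
  with ~16 detections per responsive electrode nearly all electrodes end up
  "mixed"; real studies report substantial cutaneous-only and
  proprioceptive-only minorities, which would require per-electrode modality
  heterogeneity. Pooled modality proportions and their amplitude dependence
  — the quantities the tests target — are calibrated; per-electrode class
  counts are not.
- Receptive-field consistency across amplitudes emerges only as far as the
  70% modal-cell concentration allows; strict all-response consistency for
  half the electrodes, as reported in mapping studies, is not reproduced.
- No biophysical model of current spread, no within-array somatotopy, no
  day-to-day percept drift, no psychophysical staircases: the generator
  emulates the statistical structure of session tables, not cortical
  physiology. Passing tests therefore validate the analysis machinery and
  the stated statistical structure, not claims about real cortical data.
- The KS p-value is asymptotic; for very small samples it is conservative
  relative to the exact null distribution.
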