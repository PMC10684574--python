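# Methods

`spherocal` implements the analysis chain used to phenotype neural
spheroids from intracellular calcium recordings: transient detection and
multiparametric feature extraction on population (plate-reader) traces,
single-cell network-synchrony scoring on confocal ROI matrices,
plate-level reproducibility screening and vehicle normalization, and
phenotype classification with PCA and a random forest.  A seeded
synthetic-recording generator stands in for the experimental data so
every stage can be validated against known ground truth.

## Signal model and synthetic recordings

A recording is modeled as

    F(t) = F0 · (1 + d·t/60) + Σ_k A_k · K(t − t_k) + ε(t)

with baseline `F0`, linear drift `d` (fraction per minute, photobleaching
proxy), i.i.d. Gaussian noise `ε`, and a peak-normalized
difference-of-exponentials transient kernel

    K(t) = (e^(−t/τ_d) − e^(−t/τ_r)) / K_max ,  t ≥ 0,

the simplest waveform with separate rise and decay time constants.
Event times `t_k` form a renewal process whose inter-event interval is a
refractory floor (70% of the mean interval) plus a Gamma-distributed
remainder; the mean interval is `60 / rate` and the interval SD is
`jitter_cv × mean` exactly.  The floor reflects the physiology of
network calcium oscillations — a spheroid cannot launch a new
population transient while the previous one is still rising — and it is
what makes quasi-regular traces look like the recordings these
parameters emulate rather than a Poisson process.  With probability
`ead_prob` an event carries a secondary hump on its decay limb (an
EAD-like event) at 40% of the parent amplitude, launched when the
parent kernel has decayed to 50%; both constants are fixed and mirrored
by the detector's EAD definition.

Defaults emulate the two acquisition modes of the assay: plate-reader
wells at 1.67 fps × 1000 frames (10 min), baseline 1000 a.u.; confocal
ROI sets at 1.6 fps × 480 frames (5 min), baseline 100 a.u.  The default
transient amplitude equals the baseline (~100% dF/F, typical of a
high-SNR calcium dye in an active network) and the default noise SD is
one tenth of the amplitude.  Event rate defaults to 6/min with interval
CV 0.2.

Two generator details exist so that ground truth is exactly
recoverable: the first event sits a quarter interval into the recording
(the acquisition phase is arbitrary), and an event whose kernel apex
would fall within ~7 frames of the end of the recording is not
inserted — an apex needs half a smoothing window of frames after it to
be resolvable at all.  Every simulated trace carries a sidecar listing
each inserted event's onset, on-grid apex index/time, realized (pre-
noise) amplitude and EAD flag.

Multi-ROI recordings share one population event train.  Each ROI keeps
each population event with probability `participation_p`; a non-kept
event is replaced by one at an independent uniform-random time, so
participation controls phase alignment with the population without
changing how active a cell is.  (Deleting events instead makes expected
pairwise correlation non-monotone in `participation_p`: traces with
fewer smooth transients have fewer effective degrees of freedom and a
higher random-correlation floor.)  ROIs additionally receive private
events at `independent_rate_per_min` and a per-ROI amplitude gain with
CV `roi_amplitude_cv`.

Phenotype presets encode the direction of the reported biological
contrasts — the APOE4 genotype halves the event rate, widens transients
(decay τ 6 s vs 4 s) and lowers participation (0.55 vs 0.90); chronic
µ-opioid agonist treatment of cortical spheroids lowers count and widens
peaks; opioid withdrawal in VTA-like spheroids raises count, lowers
amplitude and desynchronizes; GABAergic-only spheroids are weak and
asynchronous while dopaminergic ones are slow and broad.  Directions are
the assay's observed contrasts; magnitudes are simulator choices and are
not validated beyond their ordering.

What the generator does **not** emulate: spatial structure (no pixels or
ROI geometry), dye photophysics, bursting/irregular rhythms beyond a
single renewal process, correlated (pink) noise, or non-linear
photobleaching.  Passing tests therefore demonstrate that the analysis
chain recovers the parameters of *this* generative family; robustness to
real-instrument artifacts (focus drift, evaporation edges, motion) is
out of scope.

## Peak detection and the feature panel

The detector mirrors a plate-reader peak-analysis module with all of its
free constants fixed and documented:

* smoothing: centered moving average, window = `search_vector_length`
  frames (11), edges replicated;
* baseline: 10th percentile of the smoothed trace, plus a quantile
  de-bias term `+z_0.9 · σ_noise / √window` so a flat noisy trace is
  estimated at its true resting level;
* noise: `1.4826 · MAD(ΔF) / √2` over sub-trigger frames — difference
  detrending keeps the smooth transient waveform itself out of the
  estimate, which matters in dense-oscillation regimes where the trace
  never returns to baseline;
* trigger level: 10% above the baseline; dynamic threshold:
  baseline + 3 robust noise SDs; a peak must clear both;
* candidates: local maxima of the smoothed trace above the trigger with
  a minimum separation of one smoothing window; each candidate apex is
  refined to the raw-trace maximum within half a window, the height
  requirement is applied to the raw apex (smoothing attenuates a 4-s
  transient by ~30–40% at 1.67 fps, so testing the smoothed height
  systematically misses true events), and refined apexes that collide
  within half a window are merged keeping the larger;
* peak windows: trigger crossings of the smoothed trace bracketing the
  apex, clamped at the recording ends; windows whose apex sits on the
  boundary are discarded and logged.

Per peak: amplitude = raw apex − baseline; rise/decay times from the
trigger crossings; CTD50/CTD90 = interpolated widths at 50%/10% of
amplitude above baseline (cardiac convention — CTD90 is measured near
the baseline and is the wider; the opposite reading of "width at 90%
amplitude" is a single constant away); slopes between the interpolated
10% and 90% amplitude crossings on each limb (decay slope negative);
EAD-like count = interior local maxima on the decay limb with prominence
≥ 10% of amplitude that are not themselves detected peaks.

The per-trace panel (`FEATURE_NAMES`) holds mean/SD pairs for amplitude,
rise time, decay time, rise slope, decay slope, spacing and
instantaneous rate, plus peak count, CTD50, CTD90 and the EAD-like
count.  Missing-value policy: a trace with no peaks reports count 0 and
everything else missing (never zero); SDs require at least two peaks —
so silent wells cannot bias population summaries.  Mean rate is
count/duration per minute; rate SD is taken over per-interval
instantaneous rates (60/interval).

## Synchrony

ROI traces are normalized to F/F0 (per-ROI baseline division) and then
shifted so each trace's minimum is exactly 1, matching the reporting
convention for confocal values; the result is invariant to positive
rescaling of the raw trace.  ROIs pass an SNR filter
`(smoothed max − baseline)/σ ≥ 3`; the smoothed maximum is used because
the raw maximum of 480 frames of pure noise already sits ~3σ above
baseline and would defeat the threshold.

Synchrony is the mean squared Pearson correlation (R²) over distinct ROI
pairs.  R² is sign-blind (anti-correlation scores 1), so the signed
matrix is retained for audit.  The unit diagonal is excluded by default
(including it inflates small-n scores; a flag restores whole-matrix
averaging).  For `n` independent Gaussian traces of `T` frames the
expected score is `1/(T−1)` ≈ 0.0021 at T = 480, which the tests verify
by simulation; note that for traces dominated by a few smooth transients
the effective sample size is far below `T` and the independent-activity
floor is correspondingly higher (~0.02 under the default ROI config).

For per-ROI peak analysis a random 12-ROI subsample is drawn by
rejection sampling (uniform k-subsets, deterministic under the seed)
until its synchrony score is within 5% *relative* of the population
score; sets of ≤ 12 ROIs are returned whole.  Rejection sampling rather
than optimization preserves "random sample" semantics; attempts are
capped (default 10 000) and the failure message reports the best
deviation reached.  Zero-variance ROIs are excluded from correlation
(Pearson undefined) rather than assigned 0.

## Plate QC

The %CV screen computes `100·SD/mean` per parameter within each plate
over the vehicle-control wells (reproducibility of the assay, not
biology; a flag switches to all wells) and retains a parameter only if
its %CV is under the cutoff (30) on **every** plate — the conservative
AND across plates.  A %CV with fewer than two values or a non-positive
mean is undefined and auto-fails the parameter.

Normalization maps every value to `100 · value / control-mean` within
its plate, so control wells average exactly 100 per plate and parameter;
missing inputs stay missing, a zero/missing control mean flags the
parameter rather than inventing values, and the operation is idempotent
once applied.

Outliers are removed by the iterated two-sided Grubbs test at α = 0.05
with the critical value computed from the t-distribution closed form
`G = (n−1)/√n · √(t²/(n−2+t²))`, `t = t_{1−α/(2n), n−2}`; removal
repeats one value at a time until no rejection, never removing more than
⌊n/2⌋ values, and fewer than three values is a no-op.

## Classification

Features are standardized (the panel mixes counts, seconds and
fluorescence units) and decomposed with PCA, keeping the smallest number
of components with cumulative explained variance > 85%.  Rows with
missing values are dropped (logged), constant features removed.  An
80/20 stratified split is redrawn — sub-seeds derived deterministically
from the seed — until every per-feature Welch t-test (train vs test
scores) and per-class two-proportion z-test has p ≥ 0.05; p-values are
compared to α individually, mirroring the procedure the balance checks
come from (a Bonferroni variant would only make redraws rarer).  The
classifier is a random forest with 500 trees, unlimited depth, √k
features per split and a fixed seed; hyperparameters are configurable
but not searched.  Results are reported as a confusion matrix in row
percentages (rows sum to 100 before rounding; emitted at one decimal,
exact fractions in the JSON report), per-class and overall accuracy.
Radar summaries are per-group means of the normalized table, so the
vehicle-control group sits at 100 by construction.

## Numerical and I/O choices

All interchange is plain delimited text with a `time_s` column; floats
are written with 17 significant digits and read with round-trip parsing,
so write/read is bit-exact.  Frame rate is inferred from the time
column, which must be uniform to 1% (a skipped frame is a parse error
naming the line).  Every pipeline run writes its resolved config, a
config hash and the seed; identical configs and seeds produce
byte-identical artifacts.

Problem sizes used by the test-suite Monte-Carlo checks: 100 seeds for
noisy count recovery (±1 tolerance), 200 replicates for the noise-floor
calibration, 50 seeds per grid point for participation monotonicity,
500 heterogeneous sets for the subsampling contract, 2000 replicates for
Grubbs calibration, and 100 end-to-end replicates of a 240-well
two-genotype plate for classifier recovery.

## Known limitations

* The detector's baseline is percentile-based; in regimes where the
  trace never returns to rest (very high rate × slow decay) amplitudes
  are measured against an elevated baseline and are biased low even
  though counts remain correct.
* The minimum peak separation (one smoothing window, ~6.6 s at
  1.67 fps) bounds the resolvable event rate at ~9/min; the detector is
  not meant for fast spiking.
* EAD-like events are an operational definition (decay-limb sub-peaks at
  ≥ 10% prominence), not an electrophysiological model.
* Synchrony is zero-lag; propagating waves with consistent delays score
  lower than their physiological coordination would suggest (lag-aware
  metrics are out of scope).
* Preset magnitudes are ordinal stand-ins, not fitted kinetic constants;
  classifier accuracies on simulated contrasts say nothing quantitative
  about accuracies on experimental recordings.
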