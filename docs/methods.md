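# Methods

## Scientific setting

During cued fear extinction, a conditioned tone (CS) that previously
co-terminated with a footshock (US) is presented alone. The first second
after CS offset — the moment the expected shock fails to arrive — is the
*US-omission window*. Midbrain ventral tegmental area (VTA) dopamine (DA)
neurons emit a transient excitation in that window early in extinction, a
prediction-error-like signal that decays as the omission becomes expected,
and whose magnitude tracks how fast an animal extinguishes its fear. This
package implements the full analysis chain for that phenomenon —
single-unit electrophysiology, fiber photometry, freezing behavior, and the
statistics layer — together with a synthetic-cohort generator that supplies
inputs with the same structure, since no raw recordings of this kind are
publicly deposited.

## Session and trial model

Sessions are tone habituation (10 CS), fear conditioning (5 CS–US pairings,
US at CS offset), and extinction (25 CS by default, configurable). The CS
is 10 s; inter-trial intervals are drawn uniformly on 40–120 s; each session
opens with a 120 s baseline. Times are seconds from session start, bins are
half-open `[t, t+1)`. The ITI is defined CS offset → next CS onset (the
original rig convention is unknowable; with uniform draws the two
conventions differ only by a constant 10 s shift of the support, which no
analysis quantity depends on). Trial epochs are Hab (all habituation
trials), E-Ext (first 10 extinction trials) and L-Ext (last 10).

## Single-unit pipeline

Units are classified putative-DA when the home-cage baseline rate is
strictly below 10 Hz *and* the spike peak-to-peak width strictly above
450 µs; everything else is putative non-DA. PSTHs are aligned to CS onset,
−5…+15 s in 1 s bins (20 bins), averaged over an epoch's trials, and
z-scored against the five pre-CS baseline bins:

    z_i = (x_i − μ_b) / σ_b

with σ_b the sample SD (n−1 denominator) of the five baseline bins of the
trial-averaged PSTH. An alternative pooled-across-trials σ_b (SD of all
per-trial baseline-bin counts) is available as a config switch
(`baseline_sd="pooled_trials"`); the per-PSTH convention is the default
because the z-transform is described as operating on the averaged PSTH.
A unit with σ_b = 0 (e.g. silent through the baseline) is *unclassifiable*
and is excluded from all proportion denominators.

Response labels use strict thresholds read literally from the criteria
("greater than 2", "at least two"):

* **omission excited** — z in the first post-offset bin > 2 *and* at least
  2 above the last CS bin (rules out sustained CS excitation);
* **omission inhibited** — the mirror image;
* **CS excited / inhibited** — mean z over the ten CS bins > 2 / < −2.

The population-level check is a paired t-test across units of the raw
omission-bin rate against each unit's own baseline-bin mean (df = n − 1,
two-tailed).

## Photometry pipeline

Raw fluorescence (2 kHz) is low-pass filtered at 4 Hz and downsampled to
10 Hz. The filter is a 4th-order Butterworth applied forward–backward
(zero phase); only the cutoff is prescribed by the source analysis, so
order and type are configurable. Downsampling is non-overlapping block
averaging (factor 200) rather than decimation: block averaging is itself a
low-pass operation, so residual out-of-band power cannot alias. Measured
response: > 99.99 % attenuation at 50 Hz, ≈ 1.6 % loss at 0.5 Hz.

Per trial, F0 is the mean fluorescence over the 5 s before CS onset and
dF/F = (F − F0)/F0 on the −5…+15 s grid; dF/F is exactly invariant to
positive rescaling of the raw trace. Window statistics average over an
epoch's trials and then over the omission window (5 s after CS offset) or
the full CS. Reward responses use a 3 s pre-nosepoke baseline and the 3 s
after delivery, separately for rewarded and unrewarded pokes; a category
with no events reports NaN, never 0. The isosbestic channel is not modeled
or used, matching the analysis being reproduced. gCaMP6f and gCaMP6s
animals are pooled in epoch statistics.

## Behavior

Freezing is consumed as interval logs (merged if overlapping). Percent
freezing in a window is the covered fraction × 100, computed on continuous
time (human scoring resolution is unstated in the source; continuous time
is the natural limit). Extinction magnitude is mean E-Ext minus mean L-Ext
freezing over the CS windows. Animals below 50 % freezing (strict) on the
first extinction CS are excluded. Freezing in the 10 s after CS offset is
also reported (movement-confound control) but feeds no test.

## Statistics layer

* **Fisher's exact test (two-sided)** is implemented by direct
  hypergeometric enumeration with the point-probability rule: p is the sum
  of point probabilities ≤ the observed one, with a 1e−7 relative tie
  tolerance. This is the convention of R's `fisher.test` and scipy, and it
  reproduces the published values from the published counts: 0.00276 → 0.0028
  (10/40 vs 1/43 DA omission-excited), 1.0 (1/35 vs 1/47 non-DA), 1.0
  (2/40 vs 3/43 CS-excited), 0.1075 → 0.1 (3/40 vs 0/43 CS-inhibited).
  The remaining comparisons (printed 0.34 and 0.64) recompute to 0.348 and
  0.646 — consistent once the source's one-significant-figure truncation is
  assumed — and are reported at full precision. scipy's independent
  implementation serves as a test oracle (exhaustive for all tables with
  N ≤ 40, sampled to N = 200), alongside an exact integer-arithmetic
  enumeration whose tie handling is error-free.
* **Spearman correlation** uses tie-averaged ranks; the two-sided p-value is
  an exact full permutation enumeration for n ≤ 10 (the cohort-level n is
  10) and the t-approximation above; either can be forced, and the
  convention used is tagged in the result.
* **Paired t** is the standard two-tailed test with explicit degenerate
  contracts (all-zero differences → t = 0, p = 1; zero-variance nonzero
  differences → p = 0, flagged).
* Contingency tables count responders vs non-responders per epoch pair and
  cell class, with unclassifiable units excluded from denominators. No
  multiple-testing correction is applied, matching the analysis reproduced.
  Repeated-measures ANOVAs tied to unavailable optogenetic raw data are out
  of scope.

## Synthetic cohort

The generator's defaults are the study's conditions: 10 indicator-expressing
animals (5 gCaMP6f + 5 gCaMP6s) + 4 GFP controls; 8 units per animal per
recording day (day-1 habituation and day-2 extinction populations treated as
independent); 25 extinction trials.

**Spiking.** Inhomogeneous Poisson by thinning against the piecewise-
constant rate ceiling. Rate = baseline × CS factor, plus an additive
omission transient confined to the 1 s after CS offset with amplitude
`A·exp(−(trial−1)/τ)`. No generative model is prescribed by the source;
this is the minimal structure the analysis assumes. Defaults: DA baselines
uniform on 1.5–8.5 Hz with widths 480–650 µs (inside the classification
criterion with margin), non-DA 4–25 Hz with widths 150–430 µs (outside it);
25 % of extinction-day DA units carry an omission transient of 10–20 Hz
decaying with τ = 4 trials, so the population response is prominent in
E-Ext and back at habituation levels by L-Ext, as observed in vivo. The
source reports no effect size in Hz; these amplitudes are calibration
choices, not claims. A home-cage segment (300 s homogeneous Poisson)
provides the *measured* baseline rate the classifier consumes.

**Photometry.** A latent per-trial omission transient (peak dF/F
`a·exp(−(trial−1)/τ_learn)`) is shaped by the causal indicator kernel
`h(t) = (1 − e^(−t/τ_rise))·e^(−t/τ_decay)` (peak-normalised so amplitudes
are in dF/F units), scaled onto baseline fluorescence, plus Gaussian noise
(sd 0.3 % of baseline) and a slow sinusoidal drift (0.5 % amplitude,
300 s period), sampled at 2 kHz. Kernel defaults τ_rise = 0.05 s,
τ_decay = 0.4 s (gCaMP6f) / 1.0 s (gCaMP6s) are plausible literature-scale
constants — configurable, not fitted. GFP controls have zero signal
amplitude by constraint.

**Behavior.** Expected per-trial freezing follows
`f_end + (f_start − f_end)·exp(−(k−1)/τ_learn)` with f_start = 80 %;
realised fractions add beta noise (concentration 100, i.e. ≈ 5-point sd at
50 % freezing — a plausible scale for human-scored freezing) and are placed
as one contiguous freeze bout per CS window at a random offset.

**Copula.** Across animals, the omission amplitude `a` (uniform 0.05–0.6
dF/F) and a latent learning score are drawn through a Gaussian copula with
latent correlation `2·sin(π·ρ_s/6)`, the exact inverse of the normal-scores
Spearman relation. The learning score drives both the asymptotic freezing
level (40 → 5 %) and the extinction time constant (2 → 8 trials), over
which range the E-Ext − L-Ext change is monotone in the score, so the
latent Spearman between amplitude and expected freezing change equals the
target exactly. The measured correlation is attenuated only by the
behavioral trial noise (pre-implementation variance analysis: attenuation
factor ≈ 0.97 at the default noise, i.e. a target of 0.8 measures ≈ 0.78).

Per-entity seeds derive from the master seed by CRC32 hashing of the entity
id into a `SeedSequence`, so any unit, animal, or session can be
regenerated in isolation and cohorts are reproducible piecewise.

**What the generator does not emulate** — spike sorting and waveform shape
(width is a scalar attribute), bursting and sub-second firing structure,
photobleaching, motion artifacts and isosbestic dynamics, context
representation, and freezing scored from video. Tests passing on this
cohort show the *analysis chain* is correct under the assumed structure;
they do not validate the biological model itself.

## Numerical choices and degenerate inputs

* Spikes exactly on a bin edge belong to the right-open bin starting there.
* CS onsets are snapped to the nearest 10 Hz sample for dF/F alignment
  (≤ 50 ms error, well inside the 4 Hz bandwidth).
* σ_b = 0 → unit unclassifiable (excluded, counted, logged); F0 ≤ 0 →
  signal error; nosepokes too close to trace edges are skipped with a
  logged count; zero-margin contingency tables are degenerate with p = 1.
* Monte-Carlo problem sizes: classifier calibration uses 20 000 null units
  (standard error of the estimated false-positive rate ≈ 0.15 points
  against the 5 % bound) and 200 suprathreshold replicates; correlation
  recovery uses 200 animals. The measured false-positive rate of the
  omission-excitation criterion on homogeneous Poisson units is ≈ 4.2 % —
  slightly under the nominal one-sided 2.3 % × joint-criterion geometry
  because σ_b is estimated from only five baseline bins, making the
  statistic heavy-tailed.

## Known limitations

* The omission-transient effect sizes (Hz and dF/F) are calibration knobs;
  real effect sizes are unknown.
* The exact-permutation Spearman p is O(n!) and is auto-selected only for
  n ≤ 10.
* The pooled-σ_b convention is provided but untested against any published
  value (the source is ambiguous about which was used).
* Freezing realised as a single bout per trial is sufficient for all
  window statistics (which depend only on covered time) but is not a model
  of bout microstructure.
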