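# Methods

`tonemmn` re-implements, as a tested simulation-and-analysis pipeline, the
event-related-potential (ERP) methodology used to probe the Cantonese tone
near-merger with a passive auditory oddball paradigm: experiment design,
schematic stimulus modelling, synthetic EEG generation, preprocessing,
mismatch-negativity (MMN) and P3a quantification, and a from-scratch
spatio-temporal cluster-based permutation test. This note documents the
model, its assumptions, the parameters that matter, and the numerical and
design decisions that were genuinely open.

## Experimental design

A block presents one syllable (lexical *fu* or nonlexical *lu*) under one
tonal contrast (T1/T6 or T4/T6) with one tone as the rare deviant. Study
defaults: 535 trials per block, 80 (15%) deviants, stimulus onsets every
1200 ms (400 ms syllable + 800 ms silence), and 5–11 standards between
consecutive deviants. Eight blocks realize the 2×2×2 factorial (syllable
type × contrast × deviant role); four rotations of the block order are
supported, with lexical blocks preceding nonlexical blocks within each
contrast and deviant/standard roles swapping between consecutive blocks of
the same condition.

Two conventions are not fixed by the published design and are set here:

* **Leading standards.** Every sequence starts with at least two standards,
  so the first deviant already owns the two preceding standards that the
  trial-sorting scheme requires.
* **Trailing run.** The run after the last deviant is unconstrained (the
  gap bounds govern only runs *between* deviants).

Sequences are drawn **uniformly** over the admissible set. A
dynamic-programming table counts the compositions (leading run ≥ 2,
inter-deviant gaps in [5, 11], unconstrained tail) and each part is drawn
proportionally to the count of completions. Note that drawing gaps i.i.d.
uniform on [5, 11] and rejecting cannot work at study scale: 79 gaps have
expected sum 632 but only ≤ 453 standards are available, so admissible
sequences are a vanishing fraction of i.i.d. draws; uniform sampling of the
constrained composition is exact and O(n_gaps × n_standards). The sampler
is verified against brute-force enumeration of all admissible vectors at
small sizes.

## Stimulus model

Each 400 ms syllable has a 100 ms unvoiced onset (F0 = 0) and a 300 ms
vowel. Tones are piecewise-linear F0 trajectories constrained to reproduce
the published vowel-mean F0 values (fu1 254.9, fu4 178.6, fu6 170.9, lu1
284.7, lu4 180.2, lu6 184.3 Hz) and divergence points: T1 and T6 are level
tones, separating at the vowel onset (100 ms); T4 coincides with T6
sample-for-sample until the contrast's divergence point (200 ms for *fu*,
180 ms for *lu*) and then departs linearly, with the ramp endpoint solved
so the discrete vowel mean matches the published T4 mean exactly. The
trajectories are schematic: only the means and divergence points are
published, so the exact slopes are free parameters fixed by those
constraints.

**Divergence detection.** The detector finds the first sample from which
the absolute F0 difference exceeds the tolerance and stays above it, then
refines the onset to sub-sample precision by back-extrapolating the local
slope of the difference (clamped to one sample period). A step-like
separation (two level tones becoming voiced with different heights)
reports the first differing sample; a ramp-like departure reports the
instant the ramp leaves zero. This makes the detected divergence points
equal the defining times (100/200/180 ms) at any sampling rate, rather
than being late by one sample period, and is invariant to the sampling
rate up to one sample period.

## Synthetic EEG

The generator stands in for the study's unavailable raw recordings: a
64-channel extended 10–20 montage (the 62 enumerated cap sites plus
AF3/AF4, which the named 64-channel cap carries) sampled at 500 Hz.
Template electrode positions come from the standard 10-05 spherical
template, re-centered by a least-squares sphere fit and projected to the
unit sphere; the cerebellar leads CB1/CB2 (absent from the 10-05 set) take
the PO9/PO10 positions, the conventional stand-in for that cap's inferior
posterior leads.

**Components.** An ERP component is a Gaussian bump in time (sd
`width_ms`) with a spherical-cap spatial profile decaying with angular
distance from its fronto-central maximum (FCz), and opposite-sign weights
at the mastoids — the classic MMN source configuration whose
fronto-central amplitude *grows* under mean-mastoid re-referencing.
Amplitudes are specified in the mean-mastoid measurement reference: after
re-referencing, the component peaks at exactly `amplitude_uv` at its
topography maximum. Obligatory onset responses (N1 at 125 ms, −2 µV; P2 at
225 ms, +1.5 µV, both onset-locked) go into every trial identically and
cancel in difference waves; deviance components (MMN, P3a) are locked to
the block's divergence point and injected into deviant trials only.

Default deviance-component parameters: MMN peak 132 ms post divergence
(the study's grand-average MMN window center), temporal sd 45 ms — chosen
a priori so the component's FWHM (~106 ms) matches the reported
supra-threshold cluster span (102–188 ms) and so the spec'd
between-participant latency jitter leaves the grand average recoverable;
P3a peak 202 ms post divergence, sd 50 ms. The default effect table
encodes the study's qualitative outcome: control group — robust MMN
(−1.4 µV) plus P3a (+1.2 µV) for lexical T1/T6, weak MMN (−0.4 µV) for
lexical T4/T6 and nonlexical T1/T6, robust P3a for nonlexical T1/T6,
nothing for nonlexical T4/T6; dissociation group — robust MMN for lexical
T1/T6 only (the near-merger signature). True per-condition amplitudes are
unknown (the study reports difference-wave statistics, not ground truth);
these defaults are config-exposed and sized relative to the reported
FCz amplitude means (≈ −1 µV for lexical syllables).

**Participant variability.** Each simulated participant draws one latency
shift (normal, sd 25 ms — consistent in order of magnitude with the
reported between-participant latency SDs of 35–60 ms) and one
multiplicative amplitude factor (normal, mean 1, sd 0.25, clipped at 0),
applied to deviance components only.

**Noise and artifacts.** Background noise is stationary zero-mean white
(or 1/f) noise, independent across channels, default sd 10 µV, with an
optional 10 Hz rhythm. Artifacts are injected per trial with configurable
rates: blink transients on the frontal pole channels (150 µV, 50 ms sd),
linear drifts spanning one epoch on one channel (100 µV), and rectangular
excursions (400 µV) that violate the ±300 µV screen. What the generator
does *not* emulate: volume-conducted spatial noise correlations, real
blink/saccade morphology, alpha reactivity, electrode impedance drift, or
any brain response beyond the injected components — so passing tests show
the pipeline recovers what was injected under realistic noise levels, not
that it would behave identically on real recordings.

## Preprocessing

The chain follows the study's order, enforced by a stage flag: 1–20 Hz
bandpass on the continuous signal → 1800 ms epochs (800 ms pre-stimulus)
→ ±300 µV screening → optional ICA hook → baseline correction over the
800 ms pre-stimulus window → mean-mastoid re-reference → remaining
rejection rules. ICA is exposed only as a pass-through hook for an
external implementation and is off for synthetic data (no ocular sources
are simulated unless artifact injection is enabled).

The filter is a zero-phase Butterworth (second-order sections, order 4
effective after the forward–backward pass): passband gain within ±5% at
10 Hz, ≥ 20 dB down at 50 Hz, no group delay. On long continuous arrays
the identical squared-magnitude response is applied in the frequency
domain (`method='fft'`), which equals the forward–backward pass away from
the recording edges at a fraction of the cost; both paths are tested
against the gain bounds.

The four rejection rules the study names without formulas are
operationalized as:

* **±300 µV screen / 100 µV rule** — absolute amplitude on any channel.
* **75 µV trend** — |least-squares slope × epoch duration| > 75 µV.
* **Improbable data (5 SD)** — any sample further than 5 across-trial SDs
  from the across-trial mean at the same latency.
* **Abnormal distribution (5 SD)** — per-channel epoch kurtosis more than
  5 SDs from the across-trial kurtosis distribution.

A trial is removed when any enabled rule fires on any analysis channel;
reports carry per-rule counts and percentages. The two adaptive rules are
intentionally data-relative: on pure Gaussian noise they remove a few
percent of trials (the across-channel union of 5-SD events is not rare at
64 channels × 900 samples), which is more than the study's 0.77–2.67% on
real data; this is a property of the rule semantics, not a bug, and the
validation studies therefore use the amplitude-based rules (no artifacts
are injected there) while the adaptive rules have dedicated tests.

## Difference waves and component measures

Surviving trials sort into (i) deviants, (ii) the standard immediately
before each deviant, (iii) the standard before that, with a triplet kept
only when all three members survived rejection. True difference wave =
avg(i) − avg(ii); dummy wave = avg(ii) − avg(iii). The dummy wave is a
null reference built from physically identical stimuli: anything
surviving in it reflects labeling noise, and true − dummy is invariant to
any waveform common to all three categories.

MMN peak = most negative FCz sample of the true difference wave within
100–250 ms post divergence (earliest sample on ties; boundary peaks
flagged, not rejected). P3a peak = most positive sample strictly after
the individual MMN peak; a wave with no positive excursion returns its
least-negative sample flagged low-confidence so cohort tables stay
rectangular. Component amplitude = mean of (true − dummy) over a 100 ms
window centered on a peak; the grand-average window centers used by the
study (132, 136 and 202 ms post divergence) are available as constants,
and per-dataset recomputation is the default. Peaks are searched on the
true difference wave and amplitudes measured on true − dummy, per the
respective definitions.

## Cluster-based permutation test

Pointwise paired t-statistics over channels × time compare true vs dummy
waves across participants; points with two-tailed p < .05 are thresholded
and connected into clusters by temporal adjacency (±1 sample, same
channel) and spatial adjacency (neighboring channels, same sample; no
diagonal links), positive and negative points separately. Channel
neighborhood is great-circle distance ≤ 0.65 rad on the template sphere,
a threshold set so the median neighbor count is in the template-typical
4–8 range while the off-cap mastoids keep at least two neighbors; it is
config-exposed. Cluster mass is the sum of member t-values (sum-T).

The permutation unit is the within-participant condition exchange —
equivalently a sign flip of each participant's (true − dummy) wave, the
standard paired two-condition scheme. Each permutation contributes its
maximum positive and minimum negative cluster mass to two null
distributions; a cluster is significant when its mass falls in the outer
2.5th percentile of the matching tail. With n participants and 2^n ≤
n_permutations the test enumerates all sign assignments (exact); otherwise
it draws random assignments and uses the +1-corrected estimator
p = (1 + #{null ≥ observed}) / (n_permutations + 1), so p ≥
1/(n_permutations + 1) and the observed assignment always counts.
Marginal clusters remain in the output tagged `significant=false` so
uncorrected effects stay visible. The permutation engine recomputes t
from precomputed sums of squares (sign-flip invariant), making each
permutation one matrix product plus a sparse connected-components pass.

Numerical floor: mean differences below 1e-4 µV are treated as zero when
forming t-maps. Noise-free simulations leave single-precision rounding
residues (~1e-6 µV) with near-zero variance that would otherwise become
arbitrarily large t-values; 1e-4 µV is far below any physiological effect
and far above the rounding scale.

## Validation studies and the sizes they run at

* **Oracle equivalence.** Cluster formation is checked against a
  pure-python breadth-first-search reference on 100+ random 8×50 t-maps
  with random channel graphs, and Monte-Carlo p-values against exhaustive
  enumeration at n = 5 (agreement within 0.02). An independent
  cross-check against `mne.stats.permutation_cluster_1samp_test` verifies
  cluster membership and masses; p-value conventions differ (that
  implementation pools both tails into one max-|mass| null) so only
  qualitative significance agreement is asserted there.
* **Type-I error.** 500 wave-level null datasets (64 channels × 150
  samples of temporally smoothed Gaussian noise, n = 12, 200
  permutations): family false-alarm rate within [0.02, 0.08]. The
  sign-flip test's level depends only on exchangeability under the
  symmetric null, which the wave level preserves; a full-pipeline null at
  500 datasets would buy no additional inferential content for ~100× the
  compute.
* **Parameter recovery.** Eight replicate seeds, each a 20-participant
  cohort with an injected −1 µV MMN (132 ms post divergence, sd 45 ms,
  25 ms latency jitter, 10 µV noise, 80 deviants), run through the full
  pipeline. The grand-average *peak* understates the injected amplitude
  by design: the 1 Hz zero-phase highpass removes a fifth of a 45 ms-sd
  bump's peak and latency jitter another tenth (jointly ≈ 0.67 of the
  injected value at best, for any bump width). Amplitude recovery is
  therefore assessed by template regression — least-squares fit of the
  known jitter-convolved, filter-passed, baseline-corrected component
  shape to the grand FCz wave — which is unbiased for the injected
  amplitude; the attenuation-biased peak is reported alongside. Asserted:
  mean template-recovered amplitude within 0.2 µV of −1, mean peak
  latency within 10 ms of 132, and a significant negative cluster
  (p ≤ .025) overlapping the component's FWHM window in all replicates.
* **Qualitative pattern.** Two replicate seeds, n = 8 per group, 8 µV
  noise, 500 permutations, default effect table. Conditions with robust
  injected components must show the matching significant cluster in both
  replicates; conditions with no injected deviance response must be clean
  in at least one replicate — judging absence across replicates separates
  the permutation test's by-design 5% false alarms from injected effects.
* **Preprocessing contracts.** Baseline means zero to 1e-9 µV (double
  precision), mastoid mean identically zero after re-referencing, filter
  gain bounds at 10/50 Hz, and each rejection rule firing on a
  constructed violation.

The recovery and pattern studies epoch only the trials that can enter the
sorting triplets (each deviant plus its two preceding standards): with
per-trial rejection rules this is arithmetically identical to epoching
all 535 trials and halves the cost. Replicate counts (8 and 2) and group
sizes are the package's single-CPU sizing choices.

## Known limitations

* The noise-free "exact recovery" property (amplitude to 0.01 µV,
  latency to one sample) holds for the unfiltered chain; the 1–20 Hz
  bandpass attenuates a 45 ms-sd transient by roughly a fifth, so the
  with-filter wave is checked against the analytically filtered
  component shape and unbiased amplitude estimation uses the template
  fit described above.
* The EDF writer is minimal (16-bit, one-second records, per-channel
  scaling); it round-trips against an independent reader within one
  quantization step but does not cover EDF+ annotations.
* Electrode positions are template coordinates on a unit sphere; no
  realistic head geometry or forward model is involved, so simulated
  topographies are schematic caps, not lead-field projections.
* The cluster test covers within-group true-vs-dummy contrasts only, as
  in the study; between-group cluster tests and threshold-free cluster
  enhancement are out of scope.
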