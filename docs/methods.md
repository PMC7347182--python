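# Methods

`painemg` reimplements, end to end, a feasibility analysis of pain-intensity
prediction from facial surface electromyography (sEMG): five facial muscles
(corrugator supercilii, orbicularis oculi, levator labii superioris,
zygomaticus major, risorius) plus a frontalis noise-reference channel are
recorded at 1000 Hz while a heat or electrical (TENS) stimulus ramps up
until the subject reports first pain (t2) and then intolerable pain (t3).
The original raw recordings were never deposited, so the package ships a
calibrated synthetic cohort generator that reproduces the study's data
*structure* and headline statistics; every downstream stage also accepts
real data in the same tabular layout.

## Synthetic cohort

**Study structure.** 31 subjects × 4 tests (two heat, two electrical,
left/right), with 4 tests excluded at random from the electrical tests
(mirroring the reported equipment problems), leaving 120 analyzed tests.
Event times use a 32-s pre-stimulus lead (t1 = 32 s), and the
threshold/tolerance intervals are truncated normals per stimulus type —
heat: t2−t1 ~ N(75, 25²), t3−t2 ~ N(46.5, 20²); electrical: N(52.5, 18²)
and N(43.5, 18²), floor 8 s — scaled per subject by a lognormal factor
(σ = 0.25). These values were chosen so the cohort's test duration
(t3 − t1) has mean ≈ 110 s and SD ≈ 42 s, the only duration summary the
study reports; the heat/electrical asymmetry gives heat tests the longer
threshold period.

**Signal model.** Each muscle channel is the sum of

* a resting noise floor: unit-variance Gaussian noise band-limited to
  20–90 Hz, scaled by `floor_sigma`;
* a muscle-activity component: Gaussian noise band-limited to 20–450 Hz
  (the full surface-EMG band) multiplied by a per-sample activity
  envelope;
* shared nuisance terms: 50-Hz mains interference, sub-hertz baseline
  drift, sparse ±10σ motion spikes, and — on electrical tests — a
  biphasic 100-Hz TENS pulse train whose amplitude steps up every 3 s.

The activity envelope combines a deterministic pain ramp (corrugator:
linear from 0 at t1 to its maximum at t3; all other muscles ≈ 0 until t2,
then a linear ramp to t3), spontaneous expression bursts (Poisson onsets,
half-sine bumps; rate 0.55/s, mean amplitude 1.5 × floor), and talking
bursts on the lower-face muscles before stimulus start. The two-band
construction is deliberate: recruited muscle activity carries more
high-frequency power than the resting baseline, which is what makes the
waveform-length features slightly more period-informative than the RMS
features — matching the reported correlation ordering — whereas a single
shared carrier would make the two statistically indistinguishable after
per-test standardization.

**Population heterogeneity.** Per-subject expressiveness is lognormal
(σ = 0.65) with an extra per-muscle lognormal jitter (σ = 0.30), and 20 %
of subjects are "low-expressive" with gains scaled by 0.25. Base gains
(cor 0.85, lev 0.42, orb 0.36, zyg/ris 0.26) make the corrugator the
dominant pain muscle. Gains, burst noise and the expressiveness spread
were calibrated, as the package's study conditions, so that the full
pipeline lands at the reported performance level (nested c-index ≈ 0.63,
final ≈ 0.64, per-subject spread ≈ 0.5–0.8); the spontaneous-burst noise
is the main lever limiting predictability, the low-expressive mixture
creates the near-chance subjects.

**What the generator does not emulate:** motor-unit physiology,
stimulus dose–response, electrode placement and crosstalk, inter-channel
EMG correlation, carry-over effects between a subject's tests, and
non-stationary expressiveness within a test. Passing tests therefore show
that the pipeline recovers the statistical structure it assumes, not that
it would reach the same numbers on new real recordings.

**Determinism.** One cohort seed is split into independent structural
(profiles, durations, exclusions) and signal streams, so manifests are
identical whether or not signals are synthesized (`events_only=True` is
the fast path used for duration summaries).

## Preprocessing and features

Per test: (1) 4th-order Butterworth 20-Hz high-pass, applied
forward–backward so events stay phase-aligned (the filter order and
zero-phase application are this package's choices; only the 20-Hz
Butterworth high-pass itself is prescribed); (2) adaptive noise
cancellation with the high-pass-filtered frontalis channel as reference —
normalized LMS, 32 taps, step 0.1 (the classical reference-channel scheme;
the exact adaptive algorithm was open); (3) non-overlapping 1-s windows
aligned to recording start, reduced to RMS = √(Σx²/N) and waveform length
WL = Σ|x(i+1) − x(i)|, giving ten 1-Hz features; (4) a Hampel filter per
feature series (half-window K = 3, threshold t = 3 robust SDs via
1.4826·MAD, truncated windows at the edges); (5) per-test z-scoring with
the population SD over all labelled rows (baseline P0 included). A
zero-variance feature is set to 0 with a warning instead of propagating
NaNs. Standardization runs after labelling because its row set is defined
by the labelled interval [t0, t3].

## Period labelling

t0 = t1 − 30; t1split = t1 + ⌊(t2 − t1)/2⌋; t2split = t2 + ⌊(t3 − t2)/2⌋
(the tolerance split mirrors the threshold split). Periods: P0 = [t0, t1),
P1 = [t1, t1split], P2 = (t1split, t2), P3 = [t2, t2split],
P4 = (t2split, t3]. Rows are assigned by window-start time; rows outside
[t0, t3] are dropped. P0 is excluded from statistics and modelling
(talking contaminates it); P1 < P2 < P3 < P4 are the ordinal classes. A
test lacking any of P1–P4 (possible when t2 − t1 < 2) is excluded with a
logged reason; the default 8-s duration floor avoids this.

## Statistics

Subject-level medians per period pool each subject's tests. Pairwise
period comparisons use the Wilcoxon signed-rank test, two-sided, zeros
dropped, exact null for n ≤ 25 (normal approximation with continuity
correction otherwise, and whenever rank ties preclude the exact
distribution); no multiple-testing correction, matching the original
presentation of raw p-values. Spearman's rho (average ranks) measures
feature inter-correlations and each feature's association with the period
index. Feature screening defaults to the reported candidate set
{corrms, corwl, levwl, orbwl}; an automatic mode ranks features by
|rho| versus period and greedily drops features correlated > 0.80 with a
better-ranked keeper.

## Ordinal model and evaluation

kNN (Euclidean) on the standardized features predicts P1–P4; vote ties go
to the lower ordinal label (deterministic; a lower-label rule alone
resolves every tie). Performance is the concordance index: over row pairs
with different true labels, the fraction ordered correctly, ties credited
0.5 — 0.5 is chance, 1.0 perfect, robust to the class imbalance the
halving construction induces.

Nested leave-subject-out CV: the outer loop holds out one subject; the
inner loop, a LOSO over the remaining subjects, scores every non-empty
subset of the four candidate features × every k in {1, 3, …, 31} by the
mean inner c-index, and the argmax (ties: smaller subset, then smaller k)
is scored on the held-out subject. The aggregate is the unweighted mean of
per-subject fold c-indices (the study reports per-subject concordance with
an average line, so fold averaging rather than pair pooling). The final
model is the modal subset across outer folds with the modal k among those
folds, evaluated by plain LOSO.

Significance uses a permutation test: labels are shuffled within each test
(preserving each test's label distribution and the subject/test structure
the CV relies on), the nested CV statistic is recomputed per replicate,
and p = (1 + #{null ≥ observed}) / (1 + B) — the add-one estimator, never
exactly zero. The reference analysis used B = 1000; the shipped scripts
use B = 200, which already bounds p below 0.005 when the observed
statistic beats every replicate.

Implementation note: because permutations and fold exclusions never change
the feature geometry, each subset's neighbor lists are precomputed once
(kd-trees, top-96 neighbors cached, exact fallback when exclusions exhaust
a list) and a compiled kernel replays the CV loops. The engine is verified
against a naive pure-Python nested CV in the test suite.

## Problem sizes in the shipped checks

The acceptance script and study-level tests use 5 cohort seeds for the
duration and c-index summaries, 200 permutations for significance, and
10,000 draws for the chance baseline. Null-cohort (zero-gain) properties
run on reduced cohorts (10 subjects × 2 tests, shorter stimuli) with
19-permutation p-values, whose attainable granularity (1/20) matches the
0.05 uniformity check. These sizes are the package's own desk-scale
choices; all counts are configurable.

## Known limitations

* The generator's envelope shapes are piecewise-linear idealizations of
  the described median profiles; real expression dynamics are burstier
  and subject-specific.
* The adaptive canceller is linear (NLMS); genuinely non-linear coupling
  between reference and muscle channels is not modelled or removed.
* The c-index aggregation (fold mean) and the modal final-model rule are
  reasoned reconstructions of choices the reference analysis leaves
  unstated; both are isolated behind small functions if a different
  convention is wanted.
* With only 31 subjects the selection frequencies in the meta-learning
  stage are noisy; the modal subset can vary across cohort seeds even
  when the aggregate c-index is stable.
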