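# Methods

## Problem setting

Oculomotor dysmetria — saccades that undershoot (hypometric) or overshoot
(hypermetric) the target — is a hallmark of cerebellar ataxia. During the
clinical horizontal-saccade task the target steps 16° left or right of a
central fixation point, dwells a uniformly distributed 1.3–2.0 s, and
returns to center, for ~20 trials; the observable is the horizontal
normalized-iris-center (NIC) coordinate of each eye, sampled at 240 Hz for
42 s per subject. Since the full task (two dwells per trial) outlasts 42 s
on average, a recording is a fixed-length crop of the task; the simulator
renders exactly the target jumps that fall inside the recording window.

## Synthetic saccade generator

The generator is a first-class model of the task, not a fixture. Eye
position is a sum of smooth step transitions: each target jump elicits,
after a ~200 ms reaction latency (±20 ms jitter), a primary saccade of
amplitude *gain* × (target − eye), where the per-saccade gain is drawn from
the subject's gain distribution. The transition waveform is a logistic
sigmoid rescaled to reach its endpoints exactly (compact support, so
noiseless traces are exact staircases between transitions), with duration
following the main-sequence rule 2.2 ms/deg + 21 ms. Whenever the landing
error exceeds 10% of the step, corrective saccades follow — each after its
own latency draw (mean per subject; dysmetric subjects 0.15–0.40 s,
controls 0.12–0.18 s) and correcting ~85% of the remaining error — up to
three per jump, so severe dysmetria settles through a multi-step staircase.

Degrees map linearly to raw NIC units (16° ↔ 0.4); only linearity matters
because downstream range normalization removes absolute scale. Blinks are
Poisson events (default ~12/min) shared by both eyes, shaped as 150–250 ms
raised-cosine excursions that return exactly to the pre-blink level —
matching the definitional property the blink-removal stage keys on. Slow
drift is a <0.08 Hz sinusoid; measurement noise is white and independent
per eye.

**Binocular coupling.** The two channels share the saccade command sequence
but differ by (i) independent measurement noise, (ii) per-saccade gain
jitter on the right eye, and (iii) per-saccade onset disconjugacy (timing
jitter with sd = 0.5 × asymmetry seconds) on both primary and corrective
events. Controls carry asymmetry 0.005–0.02, dysmetric subjects 0.02–0.10,
reflecting the disconjugate saccades of cerebellar disease; this is what
gives dysmetric pairs their measurably lower correlation, h², and
coherence.

**Cohorts.** Dysmetric subjects cycle through hypometric (gain 0.50–0.84),
hypermetric (gain 1.12–1.50), and mixed modes (each saccade's gain drawn
from a hypo/hyper mixture); controls have near-unity gain 0.90–0.98. The
ranges span mild to severe disease, so cohort-level trait variance
dominates session-to-session variability — the premise of test–retest
reliability. A cohort seed spawns per-subject seeds deterministically; all
randomness in one recording flows through a single generator.

**What the generator does not emulate.** Video capture and iris tracking
(quantization, dropped frames, tracking glitches), vertical gaze, smooth
pursuit and nystagmus, fatigue or attention drift over the session, and
age/sex structure. Passing tests therefore demonstrate that the analysis
chain detects dysmetria-like kinematics under realistic noise — not
clinical performance.

## Preprocessing

Order per channel: scale to [−0.5, +0.5] → band-pass FIR → blink removal,
with a final renormalization to [−0.5, +0.5] so amplitude-threshold
statistics see the stated range. The band-pass is a 201-tap (order-200)
Hamming windowed-sinc, applied once with reflect padding and group-delay
compensation; bands are 0.08–5 Hz (single-scale features), 5–25 Hz, and
0.08–25 Hz (multiscale features). At 240 Hz an order-200 filter cannot
realize a sharp 0.08 Hz edge; the order is configurable and the limitation
accepted as part of the method definition.

Blink removal compares the signal to its order-200 running median; samples
deviating by more than 5 × MAD are grouped into events (gaps <10 samples
merged). An event is excised (replaced by the running median) only if it
lasts ≤500 ms, spans ≥3 samples, and its 50 ms-flank levels agree within
0.1 × the robust signal span — i.e., only excursions that return to their
starting level. Saccade steps and over/undershoots do not return and are
preserved by construction.

## Feature definitions and numerical choices

- **Template score.** The ideal saccade is a 0 → +0.5 → 0 pulse with 50 ms
  raised-cosine rise and a 1.5 s hold (the dwell-interval midpoint).
  Normalized cross-correlation subtracts the local window mean and divides
  by local energy, so the score is offset- and scale-invariant and lies in
  [−1, 1]. Peaks/troughs are separated by ≥1.3 s (the shortest dwell); the
  score averages the four largest peaks and four largest |troughs| — the
  extrema produced by actual saccades — falling back to all available (with
  an `incomplete` flag) when fewer exist. Temporal-order selection is
  available as a config switch.
- **Threshold surface.** Trapezoidal integration of the excess beyond
  ±0.35; thresholds configurable (±0.2…±0.4 preserve the group ordering).
- **Entropies.** Defaults m = 2, d = 1, c = 6, r = 0.2·SD, fuzzy power 2,
  kmax = 10 — the standard choices of the originating method literature.
  Dispersion classes are round-half-up of c·F(x) + 0.5 clamped to 1..c
  (equal-probability classes under the fitted normal CDF). Sample entropy
  counts template pairs with a KD-tree (Chebyshev metric, self-matches
  excluded); the degenerate no-match case returns NaN with a warning and is
  treated as missing downstream. Lempel–Ziv uses LZ76 exhaustive parsing of
  the median-binarized trace, normalized by n/log₂n.
- **Multiscale profiles.** Mean-based coarse-graining (the construction
  with the low-pass interpretation); for MDE/MFDE the normal-CDF mapping is
  fitted at scale 1 and reused at all scales (refit available), keeping
  class boundaries comparable as averaging shrinks variance.
- **Coupling.** h² uses equal-width bins over the x-range with a
  least-squares line per bin (bins with <3 points predict their mean) —
  this tracks curvature in sparse tails, where equal-count bins are widest
  exactly where nonlinearity is largest. Coherence averages Welch
  magnitude-squared coherence (4 s segments, 50% overlap, Hann) over the
  band. The Granger index fits restricted/full autoregressions by least
  squares at the BIC-selected order (≤20) and reports
  ln(σ²_restricted/σ²_full), symmetrized as the mean of both directions
  (both retained in the result). Identical channels score ~0: the index
  measures incremental predictability.
- **Statistics.** Mann–Whitney U is exact for pooled n ≤ 12 without ties,
  otherwise normal approximation with tie and continuity corrections; all
  tests two-sided. Hedges' g uses the pooled SD and the small-sample
  correction J = 1 − 3/(4N − 9). No multiple-testing correction is applied;
  per-feature p-values should be read accordingly.

## Classification

The 14 features are template score, threshold surface, DispEn (0.08–5 Hz),
h² (0.08–5 Hz), and the 10 MDE scales (0.08–25 Hz) — one feature per
best-performing family member plus the full multiscale profile.
Standardization and PCA (smallest component count with cumulative explained
variance ≥95%) are fitted inside each training fold of a seeded stratified
10-fold split; the classifier is a linear SVM with C = 1. Reported metrics
pool test-fold predictions (per-fold accuracies and their mean are also
recorded); sensitivity takes dysmetric as the positive class. Missing
feature slots are flagged, never imputed; rows with missing values are
rejected by the classifier. Age and sex are not model inputs — a known
limitation, as real cohorts differ demographically.

## Problem sizes

Desk-scale runs use 42 s recordings at 240 Hz (10,080 samples per channel).
Group statistics are demonstrated on 20/20-subject cohorts and
classification on a 72/80 cohort, with a 20-permutation label-shuffle
chance check; these sizes give stable directions of effect while keeping a
full study rerun in the low minutes on one CPU.

## Known limitations

- The 0.08 Hz band edge is nominal at order 200 (see above).
- The threshold surface detects overshoot far better than undershoot; it
  contributes one feature among 14, the others covering both polarities.
- Single-subject coupling indices overlap between groups; coupling effects
  are group-level statements.
- Synthetic accuracy (~0.9 on default cohorts) exceeds what heterogeneous
  clinical data yield; the simulator's groups are cleaner than clinical
  labels.
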