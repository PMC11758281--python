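# Methods

This note documents the models, conventions and study designs behind
`eegrep`: what the synthetic generator does and does not emulate, how each
feature pipeline is defined, the numerical choices in the persistence
computations, and the design of the validation experiments that
`scripts/acceptance.py` and the test suite run.

## Data model

An epoch is a channels × time matrix of amplitudes in μV, time-locked to one
stimulus.  The default geometry is 64 channels × 60 steps spanning −0.2 s to
1.0 s (onset at index 10); 60 samples delimit 59 intervals, so one step is
1200 ms / 59 ≈ 20.34 ms.  Amplitudes are **saturated** (not rejected) to
[−50, 50] μV, preserving the fixed epoch count per participant.
Downsampling keeps every *k*-th raw sample with no anti-alias filter: it
models subsampling of a signal that was already low-passed during
acquisition preprocessing, which is out of scope here (the generator emits
post-processed epochs; referencing, bad-channel interpolation, filtering and
ICA are deliberately not modeled).  All time indices are 0-based.

On disk, an epoch set is one `.npy` array per participant plus a single
UTF-8 CSV metadata table (one row per epoch; an empty-circle distractor's
digit is encoded as the empty string).  Round-trips are lossless to float
precision for values and exact for metadata; reads validate that every
(participant, condition, sequence) covers positions 1..*L* exactly once.

## Synthetic generator

The generator is the package's study-condition definition, not a fixture.
Defaults follow the experimental design: 42 participants, 30 sequences of
10 stimuli (exactly 5 Targets, digits uniform on 0–9, each Distractor an
empty circle with probability 0.3), 4 conditions, 1200 epochs/participant.

**Signal.**  Each epoch is a sum of ERP components plus white Gaussian
noise, clipped to ±50 μV.  A component is a half-cosine temporal bump —
smooth and compactly supported — inside its window, scaled by a Gaussian
spatial profile over the channel axis.  Windows and polarities follow the
standard post-stimulus latencies on the 60-step grid: P1 and N1 share steps
13–16 (positive occipital / negative temporo-parietal), P2 spans 17–24, P3
spans 22–35 with a parieto-occipital profile (centre at channel fraction
0.85).  Default base amplitudes are 3/4/4/2 μV for P1/N1/P2/P3.  The P3
amplitude grows by `p300_target_boost` (default 4 μV) for Targets and by
`p300_attention_scaling` (default 3 μV) when the stimulus was attended —
the generator's encoding of P300 amplitude scaling with engaged attentional
resources.  Conditions affect *behavior* only (see below), not the evoked
waveform; rhythm-induction stimuli are not generated.

**Subjects.**  Per participant: log-normal channel gains (σ = 0.2), a
half-normal latency shift (SD 10 ms), a log-normal noise-SD multiplier
around the population value (default 8 μV), a baseline attend-probability
drawn around 0.85, and condition effects on the logit of attending:
auditory support (C3) is positive for a configurable majority of subjects
(default 75%), rhythm alone (C2) has mixed sign and is more often negative,
and C4 is the C3 effect plus half the C2 effect.  Attend-probabilities are
clamped to [0.05, 0.98] to avoid degenerate all-0/all-1 participants.

**Behavior.**  Each stimulus is independently attended (Target remembered /
Distractor properly ignored) with the subject-condition probability.
Attended Targets are reported in order; unattended Targets are omitted; a
digit Distractor that was not properly ignored intrudes into the answer at
its relative position with probability `intrusion_rate` (default 0.1).
Because the behavioral score is computed from the answer string, it
reflects attention imperfectly — duplicate digits create inconclusive
stimuli and a participant can "get lucky" — which is exactly the caveat the
scoring stage documents.

**What is not emulated:** 1/f background spectra, ocular/muscle artifacts,
volume-conduction channel correlations, serial dependencies between epochs,
and any biophysical forward model.  Passing tests therefore demonstrate
that the pipelines recover effects *of the planted kind* under realistic
amplitude/noise ratios, not performance on real recordings.

**Determinism.**  A full experiment is a pure function of
(`GeneratorConfig`, seed): every subject, trial and epoch derives its own
`SeedSequence` child from the config seed.

## Attention scoring conventions

The score set is {−1, 0, 0.2, 0.4, 0.6, 0.8, 1}; fractional values occur
only for Targets.  Conventions the equations leave open were fixed as
follows:

- **Target inconclusiveness**: a Target scores −1 iff its digit also occurs
  among the sequence's digit Distractors *and* the digit appears in the
  answer — the report cannot be attributed to the Target or the Distractor.
- **Duplicate Targets**: answer occurrences are matched to Target
  occurrences of the same digit greedily left-to-right (deterministic,
  order-preserving); an unmatched occurrence scores 1.
- **Displacement** is |matched answer position − Target rank|, scored
  0.2 per position; with intrusions an answer can displace a report by more
  than 4 positions, in which case the score saturates at 1.
- **Empty circles** score −1 with precedence over the count-based clauses
  (nothing can be reported, so nothing can be concluded).

The score task keeps only the conclusive extremes, score 0 (attentive)
vs score 1 (inattentive); −1 and fractional scores are dropped.

## Feature pipelines

Lengths quoted for 64 channels × 60 steps.

- **uts** (3840): channel-by-channel concatenation of the raw series.
- **uts-rp** (230400): per-channel recurrence plot R[i,j] = |x_i − x_j|
  (absolute difference — the natural metric for a 1-D signal), flattened
  and concatenated.
- **uts-tdf** (640): per channel [max, min, mean, variance, skewness,
  excess kurtosis, N1, P1, P2, P3].  N1 is the *signed minimum* over its
  window; P1/P2/P3 are window maxima.  Moment ratios of a constant series
  (0/0) are defined as 0.  Window bounds are inclusive on both ends.
- **uts-ph** (6400): per-channel 0-dimensional sublevel-set (lower-star)
  persistence, vectorized as a 10 × 10 persistence image.
- **gfp** (60): population (not sample) standard deviation across channels
  at each time point, following the field-strength definition.
- **fbn** (2016): d_ij = 1 − Pearson(x_i, x_j), strict upper triangle,
  row-major.  A zero-variance channel has undefined correlations; these are
  set to 0 (distance 1) with a logged warning.
- **fbn-gt** (195): distances min-max normalized over the off-diagonal
  entries and thresholded at 0.1 with "≤" (small normalized distance =
  strong correlation, so the strongest connections become edges); the
  binary graph is summarized by [assortativity, average path length, edge
  connectivity] plus per-vertex [degree, betweenness, eccentricity].
  Betweenness is the unnormalized shortest-path count.  Degenerate-input
  conventions: assortativity of a regular graph (undefined correlation) is
  0; for disconnected graphs the path length is the mean of per-component
  averages, eccentricity is within-component (0 for isolated vertices), and
  edge connectivity is 0; an all-equal off-diagonal matrix is rejected
  because the normalization is undefined.  Both the normalization and the
  threshold direction are isolated in `threshold_graph` for easy revision.
- **fbn-ph** (200): the distance matrix is rank-transformed (off-diagonal
  entries replaced by their ascending rank, ties averaged), making the
  result invariant under monotone transformations of the distances, then
  filtered as a Vietoris–Rips complex; the 0- and 1-dimensional diagrams
  each become a 10 × 10 persistence image.

## Persistence: numerical choices

**Lower-star sweep.**  Plateaus (runs of equal consecutive values) are
collapsed to one sample first; this leaves sublevel-set topology unchanged
and makes "one bar per local minimum" exact.  The elder rule breaks ties by
(smaller birth value, then smaller birth index).  The global-minimum class
is essential (death ∞).

**Vietoris–Rips.**  Truncated at 2-simplices — dim-1 homology needs nothing
higher.  Dim-0 bars come from a union-find sweep over the sorted edges
(their finite deaths are exactly the MST edge weights); dim-1 bars from
boundary-matrix reduction over GF(2) with bitset columns, processing
triangles in filtration order.  Zero-persistence pairs are dropped.

**Persistence images.**  Points map to (birth, persistence) coordinates;
each contributes an isotropic Gaussian (σ = one grid-cell width by default)
weighted *linearly by persistence* — the standard choice — and the grid
integrates the surface over 10 × 10 cells via normal-CDF differences.
Essential classes are excluded: their persistence is unbounded, so any
inclusion rule would distort the linear weighting.  A consequence worth
noting: a constant signal maps to the zero image.  Image axes are fixed per
pipeline from generator-scale bounds so images are comparable across
epochs: births in [−50, 50] μV and persistence in [0, 100] μV for uts-ph;
[0, #edges] in rank units for both fbn-ph axes.

## Evaluation harness

Features are standardized with train-set mean/SD before classification —
the pipelines differ by orders of magnitude in scale.  The classifier is a
linear SVM with the conventional default regularization (C = 1) and no
hyperparameter search; the multiclass condition task uses one-vs-rest with
macro-averaged recall as balanced accuracy.  Splits (70/30, 3 repeats) are
stratified by participant × label where the strata allow it, falling back
to label-only and then unstratified, to avoid invalid single-class folds at
small quotas; `new_participants` splits subjects, never epochs.  Per-task
quota subsampling gives every participant the same number of eligible
epochs (the minimum across participants), sampled without replacement, and
is seeded so the same subsample is shared across pipelines.  Channel
selection for the high-dimensional per-channel pipelines takes the 10
channels with the largest summed |SVM coefficient| from the UTS pipeline
fitted on the complete task data (ties to the lower index).  Single-class
folds are flagged invalid, never silently scored.

## Validation studies

`eegrep.benchmarks` defines the three reference studies; problem sizes are
deliberately small (5 participants, 16 channels) because the effects are
planted per-epoch and do not require the full experiment geometry.

- **Null calibration**: all planted effects zero; attention imperfect
  (p = 0.7, intrusion 0.3) so both score classes are populated.  A
  4-task × 4-pipeline grid over 10 independently generated experiments must
  sit at chance: each cell's mean balanced accuracy is compared to a normal
  approximation of the binomial chance band at the actual test-set class
  counts, Šidák-adjusted for the 16 simultaneous cells (family-wise 5%).
  Chance is 0.5 for the binary tasks and 0.25 for the 4-class condition
  task.
- **Planted-P300 recovery**: a 5 μV Target-locked boost with the attention
  scaling at zero, 15 sequences/participant so that the score-0 ∩
  single-condition filtering still leaves a usefully large task dataset.
  The stimulus-task UTS accuracy must exceed chance at one-sided α = 0.01;
  the Distractor score task — whose epochs carry no label-linked signal
  under this configuration — is the negative control and must stay within
  a z = 3 chance band.
- **Boost monotonicity**: mean stimulus-task UTS accuracy over 5 fresh
  experiments per boost in {0, 2, 5, 10} μV must be non-decreasing within a
  0.03 sampling-error allowance.

## Known limitations

- The generator's condition effects act on behavior only; condition
  classification from EEG is at chance under the default configuration (a
  `condition → waveform` hook would require choosing auditory-evoked
  templates, which the package deliberately does not invent).
- Rank-filtration image axes span the full [0, #edges] range; diagrams of
  very sparse structure occupy few cells, which is the price of
  cross-epoch comparability.
- The scoring conventions for duplicated digits are one defensible reading
  of the ambiguous printed rules; they are centralized in `eegrep.scoring`
  and exhaustively tested against an independent counting oracle so a
  revised convention is a local change.
- Real-data mode is limited to the package's own on-disk layout; BDF/EDF
  ingestion is declared out of scope.
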