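# Methods

## Problem setting

Four-class motor-imagery (MI) classification from 22-channel EEG is the
computational core of an online rehabilitation workflow: a classifier is
pre-trained in a central location on *source* subjects, shipped to an edge
node, and adapted online to one or more *target* subjects whose trials arrive
session by session.  `edgemi` implements the full loop — synthetic (or
GDF-loaded) MI-EEG, dual-branch attention CNNs with freeze-by-index
retraining, genetic-algorithm (GA) channel selection, leave-one-subject-out
(LOSO) pre-training, and a prequential predict-then-update protocol — and is
exercised end to end on synthetic cohorts.

## Synthetic MI-EEG generator

Each trial is 7 s at a configurable sampling rate (250 Hz by default):
baseline 0–2 s, imagery 2–6 s, rest afterwards.  The signal model per channel
is

* 1/f-power ("pink") background noise at 10 µV RMS;
* one ongoing narrowband rhythm per class (Gaussian spectral envelope) on
  that class's informative channels, with amplitude set by `snr_db`
  (band-limited rhythm power over broadband noise power);
* event-related desynchronization: during the imagery interval of a trial of
  class *c*, the class-*c* rhythm amplitude drops to `sqrt(1 − depth)` with
  0.2 s cosine ramps.  Other classes' rhythms stay unmodulated.

The default montage profile places hand imagery on contralateral mu-band
(11 ± 2 Hz) sensorimotor channels, feet on midline beta (22 Hz), tongue on
bilateral central upper beta (26 Hz).

Inter-subject structure, the part that matters for transfer learning, has
three components, each parameterized and seeded per subject:

* **spatial mixing** — an orthonormal rotation `expm(s·K)` of the channel
  space with skew-symmetric `K` drawn from the subject seed
  (`mixing_strength` = 0.3 by default; 0 gives the identity).  Session 2
  receives an additional smaller rotation (`drift_per_session` = 0.1);
* **individual peak frequency** — one per-subject shift of the mu peak
  (s.d. `band_jitter_hz` = 0.75 Hz, clipped at ±2 s.d.), scaling higher
  bands proportionally;
* **class-expression variability** — per-subject, per-class multiplicative
  jitter of the ERD depth (s.d. `depth_jitter`, 0.3 in the standard
  profile), modelling the large per-class performance differences real
  subjects show.

The first component is the kind of shift a *frozen-spatial* network cannot
compensate; the latter two are the adaptable components that retrainable
stages can exploit.  Both kinds are present in real recordings; a generator
with only spatial mixing would make the late-freeze retraining protocol
unable to help in principle, which contradicts what the protocol achieves on
real data.

What the generator does **not** model: artifacts (EOG/EMG), non-stationarity
within a session, volume-conduction-realistic covariance, trial rejection
(cohorts are complete), and electrode impedance drift.  Passing tests on
synthetic cohorts therefore demonstrate the correctness and the qualitative
behaviour of the pipeline, not expected accuracy on recorded EEG.

## Model family

All variants share one dual-branch topology and differ only in the
first-stage temporal filter count F1 and kernel width KE1
(FCNNA: 96/60, XFCNN: 16/60, LFCNN: 8/48; stage 2 is 16/64 with a
16-wide separable kernel everywhere, depth multiplier 2 then 1):

* **branch A** — temporal convolution (1×KE1, F1 maps, same padding) →
  batch norm → spatial depthwise convolution over the electrodes (C×1,
  multiplier D) → batch norm → ELU → average pool (1,8) → dropout;
* **branch B** — an overcomplete temporal filter bank: (1,1) depthwise
  fan-out into 192 scaled copies → batch norm → average pool (1,8) →
  separable temporal convolution (1×16) over all electrodes, compressed to
  24 maps → batch norm → ELU → electrode-average pooling → dropout;
* branches are concatenated (2F1+24 maps) and refined by a CBAM attention
  block: channel attention (global average+max pooling through a shared MLP
  with hidden width 5·F1) ending in a pointwise projection to F1 maps, then
  spatial attention (channel mean/max maps through a (1,7) conv gate);
* **stage 2** repeats both branches at width 16 with kernel 64 and pool
  (1,2), is refined by a second CBAM block (bottleneck 4), and feeds a
  flatten → dense(4) → softmax head.

Dimensions left open by the published description (bank width, compression,
attention bottlenecks, pooling, dense size) were fixed by a constrained
search so the three variants reproduce the published footprint budgets; at
22 channels × 1125 samples the builds give 358.6K / 46.4K / 30.6K parameters
and 192.8M / 55.5M / 39.5M multiply-accumulates (printed values: 358.20K /
49.37K / 31.86K and 184M / 50M / 35M).

### Layer registry and freezing

Every layer — including zero-parameter structural nodes (input, branch taps,
concatenations, reshapes) — occupies one slot of a flat 1-based registry, so
"freeze the first L layers" is exact.  The canonical levels land on semantic
boundaries:

| level | frozen content |
|------:|----------------|
| 6  | stage-1 temporal filters |
| 16 | + all spatial filters (every channel-count-dependent parameter) |
| 26 | + the separable convolutions |
| 44 | + attention block 1's channel part and projection |

Because all channel-dependent parameters sit at indices ≤ 16, the trainable
parameter count at level ≥ 16 is invariant to the montage size (22 vs 12
channels), reproducing the published observation that channel selection does
not change the retrainable parameter count.  Freeze-44 retraining leaves
110.8K of FCNNA's parameters trainable (printed: 114.53K).

Frozen parameters receive no optimizer updates and are bit-identical after
any training run; frozen batch-norm layers also pin their running
statistics.  Backpropagation stops at the deepest trainable entry, so late
freeze levels skip the expensive stage-1 backward pass — the computational
saving the freezing strategy is for.

### Training engine

The network engine is NumPy throughout (float32), with hand-written forward
and backward passes for every layer and an Adam optimizer (β₁ = 0.9,
β₂ = 0.999).  Gradients are verified against central finite differences in
the test suite.  Inputs are standardized per trial with channel-mean removal
and a single per-trial scale, preserving relative band power across channels
(the discriminative ERD feature).  Loss is categorical cross-entropy; batch
size defaults to 64; pre-training uses learning rate 0.0009 (LR0) and, per
the reference protocol, nominally 1000 epochs with a best-checkpoint
callback (desk-scale runs use far fewer).  The checkpoint keeps the weights
of the epoch with the highest training-set accuracy evaluated in inference
mode.

## GA channel selection

Binary masks over the 22 printed channel indices (e.g. `3,8,10,11,13,15,16,
18-22`) are searched by a generational GA: tournament selection, uniform
crossover (0.8), bit-flip mutation (0.02), elitism 2, population 24, 30
generations by default, all-zero candidates repaired by one random set bit,
fitness values cached by mask key.  The algorithm is run 2–3 times and the
best mask over all evaluated individuals is kept.  The fitness of a mask is
cross-subject accuracy: train on all source subjects but one with the
masked channels, test on the held-out subject.  One mask per tested source
subject is exported and applied unchanged to all target subjects.

## LOSO pre-training and classifier selection

For each model role (architecture × channel-selection flag), each source
subject in turn is the test subject while the rest train, yielding
|subjects| classifiers per role (6 × 4 = 24 in the benchmark layout).  Two
criteria pick classifiers for transfer: highest accuracy in either
condition, and the largest accuracy improvement from channel selection; ties
break to the lower subject id.  On the published cross-subject table these
select tested subjects 3 and 1 respectively.

## Online transfer learning

Target trials are split into ordered index divisions; for the reference
600-trial stream the published boundaries are reproduced verbatim
(six: 90/90/90/90/90/150; four: 140/140/140/180); any other length splits
equally with the remainder absorbed by the last range.  A 140-trial or
90-trial session of 7 s trials lasts ⌈n·7/60⌉ = 17 or 11 minutes.

Divisions are visited subject-major (all targets' first sessions, then all
second sessions, …), retraining one shared model alternately.  Each schedule
entry:

1. **predict** the entry's trials with the last *saved* weights and record
   prequential accuracy (strictly before any update);
2. **retrain** a working copy on the subject's accumulated trials
   (instructed labels by default; pseudo-labels configurable) at the
   configured learning rate (LR0–LR3 grid: 9e-4, 1e-4, 9e-5, 1e-5), epoch
   count (30/50/100/200), and freeze level (0/6/16/26/44); a subject's first
   entry trains for 5 warm-up epochs;
3. **save if improved**: the candidate and the incumbent saved classifier
   are scored on the same monitor set and the candidate persists only if it
   is at least as accurate.

The monitor set is, by default, the held-out fraction (25%) of every seen
entry across all target subjects — the mean-accuracy-across-targets
checkpoint convention with an unbiased estimate (trained-on trials score the
candidate optimistically and are excluded).  Batch-norm running statistics
stay pinned to their pre-trained values during retraining
(`pin_bn_stats`), standard practice when fine-tuning on small batches.
Whole runs repeat `n_runs` times (default 3) with seeds s, s+1, …; reports
carry per-entry records, per-run and mean per-subject prequential
accuracies, and arithmetic group averages (all targets and each pair).

## Desk-scale reference experiments

`edgemi.experiments` packages two study-style evaluations at sizes a single
CPU handles in minutes, using a reduced variant (F1 = 8, bank 16) at 32 Hz
with a 2–6 s analysis window:

* **GA recovery** (`ga_overlap_experiment`): two source subjects, 200
  trials each, class information confined to six known channels (ERD depth
  0.6, 10 dB SNR, no mixing).  Fitness = held-out-subject accuracy after a
  6-epoch training on 160 trials, minus a 0.002/channel parsimony term
  (channel minimization is an explicit goal); GA: population 8, 6
  generations, tournament 3, mutation 0.05, initial density 0.4.  The
  selected mask's overlap with the planted set is compared with the mean
  overlap of 200 random same-size masks (the chance reference).
* **TL direction** (`tl_direction_experiment`): three source subjects
  (2×60 trials) pre-train for 25 epochs; two shifted targets (96 trials)
  run the online protocol at the headline strategy — freeze 44, four
  divisions, LR1, 30 epochs — against the frozen no-transfer baseline on
  the identical schedule.

## Numerical and design notes

* Determinism: every stochastic component takes a seed (PCG64); identical
  seeds give bit-identical cohorts, initializations, and training runs.
* Average pooling truncates a non-divisible tail (1125 → 140 → 70), as
  'valid' pooling does.
* The analysis window defaults to 2.0–6.5 s (cue-aligned 4.5 s); the offset
  is configurable since only the window length is fixed by convention.
* Division generalization (equal split, remainder to the last range) is a
  package choice; the published boundaries themselves are hard-coded for
  the 600-trial stream because no equal-split rule reproduces them.
* GDF reading goes through `mne` (optional dependency); trials are cut from
  2 s before each cue to cover the full 7 s scheme, and EOG channels are
  dropped.  No GDF writer exists in the stack, so the test suite carries a
  minimal synthetic GDF 1.25 writer for round-trip checks.
* Known limitations: CBAM dimensions and pooling are reconstructions, not
  the original implementation; the pseudo-label mode re-labels accumulated
  pools with each entry's own predictions only; the engine is CPU-bound
  NumPy and sized for desk-scale experiments, not full 1000-epoch
  pre-training on 250 Hz data.
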