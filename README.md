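# edgemi

Multi-subject transfer learning for four-class motor-imagery EEG at the
edge.

In EEG-based motor-imagery rehabilitation, a classifier is pre-trained
centrally on *source* subjects and then adapted, session by session, to the
*target* patients of an edge node.  `edgemi` implements that whole loop as a
tested library plus CLI:

* **synthetic MI-EEG** with the structure the method relies on: 22-channel,
  250 Hz, 7 s trials, class-specific ERD (band-power suppression) on
  class-specific sensorimotor channels, 1/f background noise, and seeded
  per-subject spatial mixing / spectral traits that create inter-subject
  shift (optionally, real GDF recordings via `mne`);
* **dual-branch attention CNNs** (FCNNA / XFCNN / LFCNN — EEGNet-family
  temporal + spatial convolutions in one branch, a separable temporal
  filter bank in the other, CBAM attention after each stage) with a flat
  1-based **layer registry** so that "freeze the first L layers"
  (L ∈ {0, 6, 16, 26, 44}) is exact, plus parameter and multiply-accumulate
  (MAC) accounting from the standard per-layer formulas;
* **GA channel selection** over binary masks of the 22 printed channel
  indices, scored by cross-subject accuracy;
* **leave-one-subject-out pre-training** and the two classifier-selection
  criteria (best accuracy; largest gain from channel selection);
* an **online prequential transfer-learning engine**: targets' trials are
  divided into rehabilitation sessions (six: 90/…/150 trials, four:
  140/…/180), visited in a subject-alternating schedule; each entry is
  first predicted with the saved classifier, then used to retrain it at a
  chosen learning rate (LR0–LR3), epoch count and freeze level, and the
  update persists only if it beats the incumbent on a held-out monitor.

Everything runs on NumPy (the network engine, including backpropagation, is
implemented in the package and gradient-checked in the tests).

## Worked example

```python
import edgemi as e

# 3 source + 2 target subjects, 2 sessions x 60 trials, desk scale (32 Hz)
profile = e.default_profile()          # ERD 0.5, 5 dB SNR, mixing 0.3
source, target = e.make_cohort(3, 2, profile, seed=7, n_trials=60, fs=32.0)
window = lambda c: [(s, [e.extract_window(t, 2.0, 4.0) for t in sess])
                    for s, sess in c.subjects]
source.subjects, target.subjects = window(source), window(target)

variant = e.ModelVariant("DESK", e.StageSpec(8, 16, 2, 8),
                         e.StageSpec(8, 8, 1, 8), spatial_bank=16)
clfs = e.loso_pretrain(source, variant,
                       e.TrainConfig(learning_rate=0.005, epochs=25, seed=7))
best = max(clfs, key=lambda c: c.accuracy_on_tested_subject)

sched = e.build_schedule(target.subject_ids, e.make_divisions(120, "four"))
report = e.online_tl_run(best, target, sched,
                         e.TLConfig(freeze_level=44, epochs=30,
                                    n_runs=1, seed=7))
print(report.summary())
```

prints (for this seed):

```
online transfer-learning report
----------------------------------
subject   4: prequential accuracy 0.7000
subject   5: prequential accuracy 0.7750
    AVG all: 0.7375
```

i.e. the classifier pre-trained on subjects 1–3 recognizes 70–78% of the two
target subjects' imagined movements (chance is 25%), with predictions always
made *before* the session's trials are used for retraining.

Architecture accounting for the full-size models:

```bash
$ edgemi inspect FCNNA --mac
total parameters:          358,622
trainable parameters:      358,622
total MAC:             192,819,260
$ edgemi inspect FCNNA --mac --freeze 44 | grep trainable
trainable parameters:      110,774
```

The CLI also provides `simulate`, `pretrain`, `select-channels`, `transfer`,
`report`, and `run` (a full manifest-driven experiment); every subcommand is
a thin shell over the library calls above.

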