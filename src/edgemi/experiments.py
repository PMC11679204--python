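"""Desk-scale reference experiments on synthetic cohorts.

These functions package the two study-style evaluations the library is built
for, at problem sizes a single CPU handles in minutes:

* ``ga_overlap_experiment`` — plant class information on six known channels
  and check that GA channel selection recovers them better than a random
  mask of the same size;
* ``tl_direction_experiment`` — pre-train on shifted source subjects, then
  compare online transfer learning (freeze level 44, four divisions, LR1,
  30 epochs) against the frozen no-transfer baseline on target subjects.

Model and cohort sizes here are deliberately reduced (8 temporal filters, a
16-wide filter bank, 32 Hz sampling); the architecture topology, freeze
semantics and the online protocol are identical to the full-size models.
"""

from __future__ import annotations

from typing import Dict, Tuple

import numpy as np

from .channels import ChannelMask, GAConfig, fitness_cross_subject, ga_select
from .data import (Cohort, SyntheticProfile, default_profile, extract_window,
                   make_cohort)
from .models import ModelVariant, StageSpec, TrainConfig
from .pretrain import loso_pretrain
from .transfer import (LEARNING_RATES, TLConfig, build_schedule,
                       make_divisions, online_tl_run)

__all__ = [
    "DESK_VARIANT",
    "PLANTED_CHANNELS",
    "planted_profile",
    "ga_overlap_experiment",
    "tl_direction_experiment",
]

#: reduced-width variant used by the desk-scale experiments
DESK_VARIANT = ModelVariant("DESK", StageSpec(8, 16, 2, 8),
                            StageSpec(8, 8, 1, 8), spatial_bank=16)

#: the six electrodes carrying class information in the planted profile
PLANTED_CHANNELS = (8, 9, 10, 12, 13, 16)

DESK_FS = 32.0
DESK_WINDOW = (2.0, 4.0)


def planted_profile(erd_depth: float = 0.6, snr_db: float = 10.0) -> SyntheticProfile:
    """Class information confined to six central electrodes, no mixing."""
    return SyntheticProfile(
        class_channel_map={1: (12, 13), 2: (8, 9), 3: (10, 16), 4: (9, 12)},
        band_specs={1: (11.0, 4.0, erd_depth), 2: (11.0, 4.0, erd_depth),
                    3: (22.0, 6.0, erd_depth), 4: (26.0, 6.0, erd_depth)},
        snr_db=snr_db, mixing_strength=0.0, drift_per_session=0.0,
        band_jitter_hz=0.0,
    )


def _window_cohort(cohort: Cohort, window=DESK_WINDOW) -> Cohort:
    cohort.subjects = [
        (sid, [extract_window(ts, *window) for ts in sess])
        for sid, sess in cohort.subjects
    ]
    return cohort


def ga_overlap_experiment(
    seed: int,
    n_trials_per_session: int = 100,
    fitness_trials: int = 160,
    population: int = 8,
    generations: int = 6,
) -> Dict[str, object]:
    """GA channel selection on a planted-signal cohort vs a random mask.

    Two source subjects record 2 x ``n_trials_per_session`` trials; the GA
    maximizes the accuracy of a quickly trained classifier (6 epochs on a
    ``fitness_trials`` subsample of subject 1) tested on subject 2.  Returns
    the selected mask and its overlap with the planted channels next to the
    mean overlap of random masks of the same size (the chance reference).
    """
    src, _ = make_cohort(2, 1, planted_profile(), seed=seed,
                         n_trials=n_trials_per_session, n_sessions=2,
                         fs=DESK_FS, trial_s=7.0)
    src = _window_cohort(src)
    # reduced fitness path: a fixed subsample keeps each evaluation cheap
    fit_cohort = Cohort(
        [(sid, [src.combined(sid).subset_trials(np.arange(fitness_trials))])
         for sid in src.subject_ids],
        role="source",
    )
    fit_cfg = TrainConfig(learning_rate=0.01, epochs=6, batch_size=16,
                          seed=seed)
    ga_cfg = GAConfig(population_size=population, generations=generations,
                      n_repeats=1, init_density=0.4, tournament_size=3,
                      mutation_prob=0.05, seed=seed)

    def fitness(mask: ChannelMask) -> float:
        # small parsimony term: channel minimization is part of the goal
        acc = fitness_cross_subject(mask, fit_cohort, 2, DESK_VARIANT, fit_cfg)
        return acc - 0.002 * mask.popcount

    best, history = ga_select(fitness, ga_cfg)
    planted = set(PLANTED_CHANNELS)
    # chance reference: mean overlap of random same-size masks
    rng = np.random.Generator(np.random.PCG64([seed, 0xA11CE]))
    draws = [len(set(rng.choice(22, size=best.popcount, replace=False) + 1)
                 & planted) for _ in range(200)]
    return {
        "mask": best,
        "history": history,
        "overlap_selected": len(set(best.ids) & planted),
        "overlap_random": float(np.mean(draws)),
        "popcount": best.popcount,
    }


def tl_direction_experiment(
    seed: int,
    n_source: int = 3,
    n_target: int = 2,
    source_trials: int = 60,
    target_trials: int = 96,
    pretrain_epochs: int = 25,
    tl_epochs: int = 30,
) -> Tuple[float, float]:
    """Online TL (freeze 44, four divisions, LR1, 30 epochs) vs no transfer.

    Returns (tl_accuracy, baseline_accuracy): mean prequential accuracy over
    the target subjects with and without retraining, from the same
    pre-trained classifier on the same schedule.
    """
    prof = default_profile()  # standard shift: mixing 0.3, drift 0.1
    src, tgt = make_cohort(n_source, n_target, prof, seed=seed,
                           n_trials=source_trials, n_sessions=2,
                           fs=DESK_FS, trial_s=7.0)
    src = _window_cohort(src)
    _, tgt = make_cohort(n_source, n_target, prof, seed=seed,
                         n_trials=target_trials, n_sessions=1,
                         fs=DESK_FS, trial_s=7.0)
    tgt = _window_cohort(tgt)

    clfs = loso_pretrain(
        src, DESK_VARIANT,
        TrainConfig(learning_rate=0.005, epochs=pretrain_epochs,
                    batch_size=32, seed=seed),
    )
    best = max(clfs, key=lambda c: c.accuracy_on_tested_subject)

    n_stream = min(tgt.combined(s).n_trials for s in tgt.subject_ids)
    schedule = build_schedule(tgt.subject_ids, make_divisions(n_stream, "four"))
    baseline = online_tl_run(
        best, tgt, schedule,
        TLConfig(freeze_level=44, epochs=0, warmup_epochs=0, n_runs=1,
                 seed=seed),
    )
    tl = online_tl_run(
        best, tgt, schedule,
        TLConfig(freeze_level=44, learning_rate=LEARNING_RATES["LR1"],
                 epochs=tl_epochs, warmup_epochs=5, batch_size=8, n_runs=1,
                 seed=seed),
    )
    return tl.group_average["AVG all"], baseline.group_average["AVG all"]
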