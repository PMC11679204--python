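"""Online multi-subject transfer learning at the edge.

A pre-trained classifier is adapted to several target subjects whose trials
are split into ordered "rehabilitation sessions" (index divisions).  Sessions
are visited in a subject-alternating schedule; at each schedule entry the
currently saved classifier first predicts the entry's trials (prequential
accuracy, measured strictly before any update), is then retrained on the
subject's accumulated trials at the configured learning rate, epoch count and
freeze level, and is persisted only if its monitored accuracy improved.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .data import Cohort, TrialSet, drop_channels
from .models import (ModelHandle, TrainConfig, predict, set_freeze_level,
                     train)
from .pretrain import PretrainedClassifier

__all__ = [
    "DivisionScheme",
    "TLConfig",
    "Schedule",
    "TLReport",
    "LEARNING_RATES",
    "make_divisions",
    "build_schedule",
    "online_tl_run",
    "group_averages",
    "session_minutes",
]

# the learning-rate grid of the retraining experiments
LEARNING_RATES = {"LR0": 0.0009, "LR1": 0.0001, "LR2": 0.00009, "LR3": 0.00001}

# printed division boundaries for the reference 600-trial target stream
_PRINTED = {
    ("six", 600): ((0, 90), (90, 180), (180, 270), (270, 360), (360, 450),
                   (450, 600)),
    ("four", 600): ((0, 140), (140, 280), (280, 420), (420, 600)),
}
_N_DIVISIONS = {"six": 6, "four": 4}


@dataclass(frozen=True)
class DivisionScheme:
    name: str
    boundaries: Tuple[Tuple[int, int], ...]

    def __post_init__(self):
        prev = 0
        for lo, hi in self.boundaries:
            if lo != prev or hi <= lo:
                raise ValueError("ranges must be disjoint, ordered and cover [0,n)")
            prev = hi

    @property
    def n_trials(self) -> int:
        return self.boundaries[-1][1]


def make_divisions(n_trials: int, scheme_name: str) -> DivisionScheme:
    """Session index ranges.  For the reference 600-trial stream the printed
    boundaries are reproduced verbatim; otherwise trials are split equally
    with the remainder absorbed by the last (largest) range."""
    if scheme_name not in _N_DIVISIONS:
        raise ValueError("scheme must be 'six' or 'four'")
    d = _N_DIVISIONS[scheme_name]
    if n_trials < d:
        raise ValueError(f"{n_trials} trials cannot form {d} divisions")
    if (scheme_name, n_trials) in _PRINTED:
        return DivisionScheme(scheme_name, _PRINTED[(scheme_name, n_trials)])
    size = n_trials // d
    bounds = [(i * size, (i + 1) * size) for i in range(d - 1)]
    bounds.append(((d - 1) * size, n_trials))
    return DivisionScheme(scheme_name, tuple(bounds))


@dataclass(frozen=True)
class Schedule:
    """Subject-alternating order of (subject_id, division_range) entries."""

    entries: Tuple[Tuple[int, Tuple[int, int]], ...]

    def __len__(self) -> int:
        return len(self.entries)


def build_schedule(target_ids: Sequence[int],
                   divisions: DivisionScheme) -> Schedule:
    """All targets' first sessions, then all second sessions, and so on."""
    if not target_ids:
        raise ValueError("no target subjects")
    entries = []
    for rng in divisions.boundaries:
        for sid in target_ids:
            entries.append((sid, rng))
    return Schedule(tuple(entries))


@dataclass(frozen=True)
class TLConfig:
    freeze_level: int = 44
    learning_rate: float = LEARNING_RATES["LR1"]
    epochs: int = 30
    warmup_epochs: int = 5
    label_mode: str = "instructed"
    accumulate: bool = True
    monitor: str = "pool"      # "pool": mean accuracy over all targets' seen
    n_runs: int = 3            # trials (checkpoint convention); "entry":
    batch_size: int = 64       # accuracy on the current entry only
    holdout_frac: float = 0.25  # per-entry fraction reserved for the monitor
    pin_bn_stats: bool = True  # keep pre-trained normalization statistics
    seed: int = 0              # (never trained on); 0 monitors on the pool

    def __post_init__(self):
        if self.label_mode not in ("instructed", "pseudo"):
            raise ValueError("label_mode must be 'instructed' or 'pseudo'")
        if self.monitor not in ("pool", "entry"):
            raise ValueError("monitor must be 'pool' or 'entry'")
        if not 0.0 <= self.holdout_frac < 1.0:
            raise ValueError("holdout_frac must lie in [0,1)")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")


@dataclass
class EntryRecord:
    run: int
    step: int
    subject: int
    division: Tuple[int, int]
    n_trials: int
    n_correct: int
    accuracy: float
    monitored_accuracy: float    # candidate model on the monitor set
    incumbent_accuracy: float    # last saved model on the same monitor set
    saved: bool
    wall_time_s: float


@dataclass
class TLReport:
    """Prequential accuracies per schedule entry, per subject, and averaged."""

    entries: List[EntryRecord] = field(default_factory=list)
    per_run_subject_accuracy: List[Dict[int, float]] = field(default_factory=list)
    subject_accuracy: Dict[int, float] = field(default_factory=dict)
    group_average: Dict[str, float] = field(default_factory=dict)

    def finalize(self, target_ids: Sequence[int]) -> None:
        runs = sorted({e.run for e in self.entries})
        self.per_run_subject_accuracy = []
        for r in runs:
            accs = {}
            for sid in target_ids:
                rec = [e for e in self.entries if e.run == r and e.subject == sid]
                n = sum(e.n_trials for e in rec)
                accs[sid] = sum(e.n_correct for e in rec) / n if n else float("nan")
            self.per_run_subject_accuracy.append(accs)
        self.subject_accuracy = {
            sid: float(np.mean([a[sid] for a in self.per_run_subject_accuracy]))
            for sid in target_ids
        }
        self.group_average = group_averages(self, list(target_ids))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.entries])

    def summary(self) -> str:
        lines = ["online transfer-learning report", "-" * 34]
        for sid, acc in self.subject_accuracy.items():
            lines.append(f"subject {sid:>3}: prequential accuracy {acc:.4f}")
        for name, acc in self.group_average.items():
            lines.append(f"{name:>11}: {acc:.4f}")
        return "\n".join(lines)


def group_averages(report: TLReport, target_ids: Sequence[int]) -> Dict[str, float]:
    """Arithmetic means over all targets and over each target pair."""
    accs = report.subject_accuracy
    unknown = [s for s in target_ids if s not in accs]
    if unknown:
        raise KeyError(f"no accuracy recorded for subjects {unknown}")
    out = {"AVG all": float(np.mean([accs[s] for s in target_ids]))}
    if len(target_ids) > 2:
        for i, a in enumerate(target_ids):
            for b in target_ids[i + 1:]:
                out[f"AVG {a}{b}"] = float((accs[a] + accs[b]) / 2.0)
    return out


def session_minutes(n_trials: int, trial_s: float) -> int:
    """Rehabilitation-session duration in whole minutes (ceiling)."""
    if n_trials <= 0 or trial_s <= 0:
        raise ValueError("n_trials and trial_s must be positive")
    import math

    return math.ceil(n_trials * trial_s / 60.0)


def _monitored_accuracy(model, streams, monitor_sets, pseudo, tl_cfg,
                        sid) -> float:
    """Checkpoint monitor for save-if-improved.

    ``pool`` mode follows the checkpoint convention of monitoring the mean
    accuracy across the target subjects' trials seen so far (their held-out
    fractions when ``holdout_frac`` > 0); ``entry`` mode scores only the
    current subject's monitor set.
    """
    subjects = [sid] if tl_cfg.monitor == "entry" else list(monitor_sets)
    per_subject = []
    for s in subjects:
        idx = monitor_sets.get(s, [])
        if not idx:
            continue
        block = streams[s].subset_trials(np.array(idx))
        labels, _ = predict(model, block, batch=64)
        if tl_cfg.label_mode == "instructed":
            reference = block.labels
        else:
            reference = np.array([pseudo[s][i] for i in idx])
        per_subject.append(float((labels == reference).mean()))
    return float(np.mean(per_subject)) if per_subject else 0.0


def online_tl_run(
    pretrained: PretrainedClassifier,
    targets: Cohort,
    schedule: Schedule,
    tl_cfg: TLConfig,
    post_update_hook: Optional[Callable[[int, ModelHandle], None]] = None,
) -> TLReport:
    """Prequential predict-then-update over the schedule, repeated n_runs times.

    Each run starts from the pre-trained weights.  Predictions for an entry
    always come from the last *saved* weights; an update whose monitored
    accuracy does not improve on the best so far is discarded.  The first
    entry of each subject trains for ``warmup_epochs``; later entries for
    ``tl_cfg.epochs``.  ``post_update_hook(step, model)`` may mutate the
    working model after each update (used to assert prequential integrity).
    """
    mask = pretrained.mask
    target_ids = sorted({sid for sid, _ in schedule.entries})
    streams: Dict[int, TrialSet] = {}
    for sid in target_ids:
        ts = drop_channels(targets.combined(sid), mask)
        if (ts.n_channels != pretrained.model.n_channels
                or ts.n_samples != pretrained.model.n_samples):
            raise ValueError(
                "masked target trials do not match the pretrained classifier "
                f"input ({ts.n_channels} ch x {ts.n_samples} samp vs "
                f"{pretrained.model.n_channels} x {pretrained.model.n_samples})"
            )
        needed = max(hi for s, (lo, hi) in schedule.entries if s == sid)
        if ts.n_trials < needed:
            raise ValueError(
                f"subject {sid} has {ts.n_trials} trials, schedule needs {needed}"
            )
        streams[sid] = ts

    report = TLReport()
    for run in range(tl_cfg.n_runs):
        run_seed = tl_cfg.seed + run
        saved = pretrained.model.copy()
        saved.pin_bn_stats = tl_cfg.pin_bn_stats
        set_freeze_level(saved, tl_cfg.freeze_level)
        pools: Dict[int, List[int]] = {sid: [] for sid in target_ids}
        monitor_sets: Dict[int, List[int]] = {sid: [] for sid in target_ids}
        pseudo: Dict[int, Dict[int, int]] = {sid: {} for sid in target_ids}
        seen: Dict[int, bool] = {sid: False for sid in target_ids}
        mod = (round(1.0 / tl_cfg.holdout_frac)
               if tl_cfg.holdout_frac > 0 else 0)
        for step, (sid, (lo, hi)) in enumerate(schedule.entries):
            t0 = time.perf_counter()
            stream = streams[sid]
            block = stream.subset_trials(np.arange(lo, hi))
            pred_labels, _ = predict(saved, block)
            n_correct = int((pred_labels == block.labels).sum())
            acc = n_correct / block.n_trials

            if tl_cfg.label_mode == "pseudo":
                pseudo[sid].update(zip(range(lo, hi), pred_labels.tolist()))
            entry_idx = list(range(lo, hi))
            if mod:
                held = entry_idx[mod - 1::mod]
                entry_train = [i for i in entry_idx if i not in held]
            else:
                held, entry_train = entry_idx, entry_idx
            monitor_sets[sid].extend(held)
            if tl_cfg.accumulate:
                pools[sid].extend(entry_train)
                train_idx = np.array(pools[sid])
            else:
                train_idx = np.array(entry_train)
            train_block = stream.subset_trials(train_idx)
            if tl_cfg.label_mode == "pseudo":
                train_block = TrialSet(
                    train_block.data,
                    np.array([pseudo[sid][i] for i in train_idx]),
                    train_block.montage, train_block.subject_id,
                    train_block.session_id, train_block.window,
                )

            epochs = tl_cfg.warmup_epochs if not seen[sid] else tl_cfg.epochs
            seen[sid] = True
            working = saved.copy()
            monitored = incumbent = acc
            if epochs > 0:
                rep = train(working, train_block, TrainConfig(
                    learning_rate=tl_cfg.learning_rate, epochs=epochs,
                    batch_size=tl_cfg.batch_size, seed=run_seed * 1009 + step,
                ))
                if post_update_hook is not None:
                    post_update_hook(step, working)
                # paired save-if-improved: candidate vs the incumbent saved
                # classifier, scored on the same monitor set
                monitored = _monitored_accuracy(
                    working, streams, monitor_sets, pseudo, tl_cfg, sid)
                incumbent = _monitored_accuracy(
                    saved, streams, monitor_sets, pseudo, tl_cfg, sid)
            do_save = epochs > 0 and monitored >= incumbent
            if do_save:
                saved = working
            report.entries.append(EntryRecord(
                run=run, step=step, subject=sid, division=(lo, hi),
                n_trials=block.n_trials, n_correct=n_correct, accuracy=acc,
                monitored_accuracy=monitored, incumbent_accuracy=incumbent,
                saved=do_save, wall_time_s=time.perf_counter() - t0,
            ))
    report.finalize(target_ids)
    return report
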