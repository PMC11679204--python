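"""Experiment manifests: a flat YAML schema driving the full pipeline.

A manifest snapshots every knob of a simulate -> pretrain -> (select
channels) -> transfer -> report run, so re-running it reproduces all
deterministic outputs bit-identically.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import yaml

from . import __version__
from .channels import ChannelMask, GAConfig, fitness_cross_subject, ga_select
from .data import default_profile, extract_window, make_cohort, save_cohort
from .models import TrainConfig, get_variant
from .pretrain import loso_pretrain
from .transfer import (LEARNING_RATES, TLConfig, build_schedule,
                       make_divisions, online_tl_run)

log = logging.getLogger("edgemi")

_SCHEMA: Dict[str, type] = {
    # cohort simulation
    "n_source": int, "n_target": int, "n_trials_per_session": int,
    "n_sessions": int, "fs": float, "trial_s": float, "erd_depth": float,
    "snr_db": float, "mixing_strength": float, "drift_per_session": float,
    # windowing
    "window_start_s": float, "window_dur_s": float,
    # model / pre-training
    "variant": str, "channel_selection": bool, "pretrain_epochs": int,
    "pretrain_lr": float, "batch_size": int, "spatial_bank": int,
    # channel selection
    "ga_population": int, "ga_generations": int, "ga_repeats": int,
    "ga_fitness_epochs": int,
    # transfer learning
    "divisions": str, "freeze_level": int, "learning_rate": str,
    "tl_epochs": int, "warmup_epochs": int, "label_mode": str, "n_runs": int,
    # bookkeeping
    "seed": int, "out_dir": str,
}

_DEFAULTS = {
    "n_source": 6, "n_target": 3, "n_trials_per_session": 288,
    "n_sessions": 2, "fs": 250.0, "trial_s": 7.0, "erd_depth": 0.5,
    "snr_db": 5.0, "mixing_strength": 0.3, "drift_per_session": 0.1,
    "window_start_s": 2.0, "window_dur_s": 4.5,
    "variant": "FCNNA", "channel_selection": False, "pretrain_epochs": 1000,
    "pretrain_lr": 0.0009, "batch_size": 64, "spatial_bank": 192,
    "ga_population": 24, "ga_generations": 30, "ga_repeats": 2,
    "ga_fitness_epochs": 5,
    "divisions": "four", "freeze_level": 44, "learning_rate": "LR1",
    "tl_epochs": 30, "warmup_epochs": 5, "label_mode": "instructed",
    "n_runs": 3, "seed": 0, "out_dir": "edgemi_out",
}


@dataclass
class ExperimentManifest:
    """Validated configuration snapshot for one end-to-end experiment."""

    values: Dict[str, object] = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: Dict[str, object]) -> "ExperimentManifest":
        raw = {k: v for k, v in raw.items() if not k.startswith("_")}
        bad_keys = sorted(set(raw) - set(_SCHEMA))
        if bad_keys:
            raise ValueError(f"unknown manifest keys: {bad_keys}")
        values = dict(_DEFAULTS)
        errors = []
        for k, v in raw.items():
            want = _SCHEMA[k]
            try:
                values[k] = want(v) if not isinstance(v, want) else v
            except (TypeError, ValueError):
                errors.append(f"{k}: expected {want.__name__}, got {v!r}")
        if values["learning_rate"] not in LEARNING_RATES:
            try:
                values["learning_rate"] = float(values["learning_rate"])
            except ValueError:
                errors.append(
                    f"learning_rate: {values['learning_rate']!r} is neither "
                    f"one of {sorted(LEARNING_RATES)} nor a number")
        if values["divisions"] not in ("six", "four"):
            errors.append("divisions: must be 'six' or 'four'")
        if errors:
            raise ValueError("manifest validation failed: " + "; ".join(errors))
        return cls(values)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentManifest":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        payload = dict(self.values)
        payload["_package_version"] = __version__
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    def __getitem__(self, key):
        return self.values[key]


def run_experiment(manifest: ExperimentManifest) -> Dict[str, object]:
    """simulate -> pretrain -> (select channels) -> transfer -> report.

    Returns a dict of artifacts (cohorts, classifiers, report) and writes
    the manifest snapshot plus a JSON report beside the outputs.
    """
    m = manifest
    out_dir = Path(m["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(m["seed"])

    log.info("simulate: %d source / %d target subjects", m["n_source"], m["n_target"])
    profile = default_profile(
        erd_depth=m["erd_depth"], snr_db=m["snr_db"],
        mixing_strength=m["mixing_strength"],
        drift_per_session=m["drift_per_session"],
    )
    source, target = make_cohort(
        m["n_source"], m["n_target"], profile, seed=seed,
        n_trials=m["n_trials_per_session"], n_sessions=m["n_sessions"],
        fs=m["fs"], trial_s=m["trial_s"],
    )
    save_cohort(out_dir / "cohort.h5", {"source": source, "target": target})

    def window(cohort):
        subs = [
            (sid, [extract_window(ts, m["window_start_s"], m["window_dur_s"])
                   for ts in sessions])
            for sid, sessions in cohort.subjects
        ]
        return type(cohort)(subs, role=cohort.role)

    source_w, target_w = window(source), window(target)

    variant = get_variant(m["variant"]).with_channel_selection(
        bool(m["channel_selection"]))
    if int(m["spatial_bank"]) != variant.spatial_bank:
        from dataclasses import replace
        variant = replace(variant, spatial_bank=int(m["spatial_bank"]))
    train_cfg = TrainConfig(
        learning_rate=m["pretrain_lr"], epochs=m["pretrain_epochs"],
        batch_size=m["batch_size"], seed=seed,
    )

    mask_provider = None
    if variant.uses_channel_selection:
        log.info("select-channels: GA over %d-channel masks",
                 source_w.combined(source_w.subject_ids[0]).n_channels)
        fit_cfg = TrainConfig(
            learning_rate=m["pretrain_lr"], epochs=m["ga_fitness_epochs"],
            batch_size=m["batch_size"], seed=seed,
        )
        masks: Dict[int, ChannelMask] = {}

        def mask_provider(sid: int) -> ChannelMask:
            if sid not in masks:
                ga_cfg = GAConfig(
                    population_size=m["ga_population"],
                    generations=m["ga_generations"],
                    n_repeats=m["ga_repeats"],
                    n_channels=source_w.combined(sid).n_channels,
                    seed=seed * 131 + sid,
                )
                masks[sid], _ = ga_select(
                    lambda mk: fitness_cross_subject(
                        mk, source_w, sid, variant, fit_cfg),
                    ga_cfg,
                )
                (out_dir / f"mask_subject{sid}.txt").write_text(
                    masks[sid].to_string() + "\n")
            return masks[sid]

    log.info("pretrain: leave-one-subject-out, variant %s", variant.name)
    classifiers = loso_pretrain(source_w, variant, train_cfg, mask_provider)
    best = max(classifiers, key=lambda c: c.accuracy_on_tested_subject)

    lr = m["learning_rate"]
    tl_cfg = TLConfig(
        freeze_level=m["freeze_level"],
        learning_rate=LEARNING_RATES.get(lr, lr if isinstance(lr, float) else 0.0001),
        epochs=m["tl_epochs"], warmup_epochs=m["warmup_epochs"],
        label_mode=m["label_mode"], n_runs=m["n_runs"],
        batch_size=m["batch_size"], seed=seed,
    )
    n_stream = min(target_w.combined(sid).n_trials for sid in target_w.subject_ids)
    divisions = make_divisions(n_stream, m["divisions"])
    schedule = build_schedule(target_w.subject_ids, divisions)
    log.info("transfer: %d schedule entries, freeze %d, lr %s, %d epochs",
             len(schedule), tl_cfg.freeze_level, m["learning_rate"], tl_cfg.epochs)
    report = online_tl_run(best, target_w, schedule, tl_cfg)

    manifest.to_yaml(out_dir / "manifest.yaml")
    report_payload = {
        "pretrained": {
            "variant": variant.name,
            "tested_source_subject": best.tested_source_subject,
            "accuracy_on_tested_subject": best.accuracy_on_tested_subject,
            "loso_accuracies": {
                c.tested_source_subject: c.accuracy_on_tested_subject
                for c in classifiers
            },
        },
        "subject_accuracy": report.subject_accuracy,
        "group_average": report.group_average,
        "entries": [vars(e) for e in report.entries],
    }
    (out_dir / "report.json").write_text(
        json.dumps(report_payload, indent=2, default=float))
    return {
        "source": source_w, "target": target_w, "classifiers": classifiers,
        "report": report, "out_dir": out_dir,
    }
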