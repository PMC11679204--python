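"""Leave-one-subject-out pre-training over the source cohort.

For each model variant, every source subject in turn is held out for testing
while the remaining subjects form the training set, yielding one pre-trained
classifier per (variant, tested subject).  Two selection criteria pick the
classifiers carried forward to transfer learning: the highest accuracy, and
the largest accuracy improvement from channel selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Dict, List, Optional, Tuple

from .channels import ChannelMask
from .data import Cohort, TrialSet, drop_channels
from .models import (ModelHandle, ModelVariant, TrainConfig, build_model,
                     load_checkpoint, predict, save_checkpoint, train)

__all__ = ["PretrainedClassifier", "loso_pretrain", "pick_classifiers",
           "save_classifier", "load_classifier"]


@dataclass
class PretrainedClassifier:
    model: ModelHandle
    variant: ModelVariant
    tested_source_subject: int
    mask: ChannelMask
    accuracy_on_tested_subject: float

    def __post_init__(self):
        if not 0.0 <= self.accuracy_on_tested_subject <= 1.0:
            raise ValueError("accuracy must lie in [0,1]")


def loso_pretrain(
    source_cohort: Cohort,
    variant: ModelVariant,
    train_cfg: TrainConfig,
    mask_provider: Optional[Callable[[int], ChannelMask]] = None,
) -> List[PretrainedClassifier]:
    """One classifier per source subject (as the tested subject).

    ``mask_provider`` maps a tested subject id to its channel mask; when the
    variant uses channel selection it must be supplied (typically the GA
    result for that subject).  Without channel selection the all-ones mask
    is used.
    """
    ids = source_cohort.subject_ids
    if len(ids) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 source subjects")
    n_channels = source_cohort.combined(ids[0]).n_channels
    out = []
    for sid in ids:
        if variant.uses_channel_selection:
            if mask_provider is None:
                raise ValueError(
                    "variant uses channel selection but no mask_provider given"
                )
            mask = mask_provider(sid)
        else:
            mask = ChannelMask.all_ones(n_channels)
        train_data = TrialSet.concatenate([
            drop_channels(source_cohort.combined(other), mask)
            for other in ids if other != sid
        ])
        test_data = drop_channels(source_cohort.combined(sid), mask)
        model = build_model(variant, train_data.n_channels,
                            train_data.n_samples, seed=train_cfg.seed)
        train(model, train_data, train_cfg)
        labels, _ = predict(model, test_data)
        acc = float((labels == test_data.labels).mean())
        out.append(PretrainedClassifier(model, variant, sid, mask, acc))
    return out


def pick_classifiers(results_no_cs: Dict[int, float],
                     results_cs: Dict[int, float]) -> Tuple[int, int]:
    """The two selection criteria over per-tested-subject accuracies.

    Returns (best_subject, most_improved_subject): the tested subject with
    the highest accuracy under either condition, and the one with the
    largest accuracy gain from channel selection.  Ties break toward the
    lower subject id.
    """
    if set(results_no_cs) != set(results_cs):
        raise ValueError("tested-subject sets differ between conditions")
    if not results_no_cs:
        raise ValueError("empty result lists")
    subjects = sorted(results_no_cs)
    best = max(subjects,
               key=lambda s: (max(results_no_cs[s], results_cs[s]), -s))
    improved = max(subjects,
                   key=lambda s: (results_cs[s] - results_no_cs[s], -s))
    return best, improved


def save_classifier(clf: PretrainedClassifier, directory) -> None:
    """Classifier bundle: checkpoint + mask file + metadata manifest."""
    import json

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    save_checkpoint(clf.model, directory / "checkpoint")
    (directory / "mask.txt").write_text(clf.mask.to_string() + "\n")
    meta = {
        "variant": clf.variant.name,
        "uses_channel_selection": clf.variant.uses_channel_selection,
        "tested_source_subject": clf.tested_source_subject,
        "accuracy_on_tested_subject": clf.accuracy_on_tested_subject,
        "n_mask_channels": clf.mask.popcount,
        "mask_length": len(clf.mask.bits),
    }
    (directory / "meta.json").write_text(json.dumps(meta, indent=2))


def load_classifier(directory) -> PretrainedClassifier:
    import json

    directory = Path(directory)
    model = load_checkpoint(directory / "checkpoint")
    meta = json.loads((directory / "meta.json").read_text())
    mask = ChannelMask.from_string((directory / "mask.txt").read_text(),
                                   n_channels=meta.get("mask_length", 22))
    return PretrainedClassifier(
        model, model.variant, meta["tested_source_subject"], mask,
        meta["accuracy_on_tested_subject"],
    )
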