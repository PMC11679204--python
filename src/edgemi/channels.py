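"""Genetic-algorithm search over binary electrode masks.

The search maximizes cross-subject validation accuracy: a candidate mask is
scored by training a model on all source subjects except one and testing on
the held-out subject using only the masked channels.  The algorithm is run
two to three times and the best mask over all evaluated individuals is kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Sequence, Tuple

import numpy as np

from .data import Cohort, TrialSet, drop_channels
from .models import ModelVariant, TrainConfig, build_model, predict, train

__all__ = ["ChannelMask", "GAConfig", "GAHistory", "ga_select",
           "fitness_cross_subject"]


@dataclass(frozen=True)
class ChannelMask:
    """Binary selection over the montage, printed as 1-based channel ids."""

    bits: Tuple[int, ...]

    def __post_init__(self):
        if not self.bits or any(b not in (0, 1) for b in self.bits):
            raise ValueError("mask bits must be 0/1 and non-empty")
        if sum(self.bits) < 1:
            raise ValueError("mask must select at least one channel")

    @classmethod
    def from_ids(cls, ids: Sequence[int], n_channels: int = 22) -> "ChannelMask":
        bits = [0] * n_channels
        for i in ids:
            if not 1 <= i <= n_channels:
                raise ValueError(f"channel id {i} outside 1..{n_channels}")
            bits[i - 1] = 1
        return cls(tuple(bits))

    @classmethod
    def from_string(cls, text: str, n_channels: int = 22) -> "ChannelMask":
        """Parse the printed notation, e.g. ``3,8,10,11,13,15,16,18-22``."""
        ids: List[int] = []
        for tok in text.replace("[", "").replace("]", "").split(","):
            tok = tok.strip().replace("–", "-")
            if not tok:
                continue
            if "-" in tok:
                lo, hi = tok.split("-")
                ids.extend(range(int(lo), int(hi) + 1))
            else:
                ids.append(int(tok))
        return cls.from_ids(ids, n_channels)

    @classmethod
    def all_ones(cls, n_channels: int = 22) -> "ChannelMask":
        return cls(tuple([1] * n_channels))

    @property
    def ids(self) -> Tuple[int, ...]:
        return tuple(i + 1 for i, b in enumerate(self.bits) if b)

    @property
    def popcount(self) -> int:
        return sum(self.bits)

    def to_string(self) -> str:
        """Printed notation with runs compressed (``18,19,20`` -> ``18-20``)."""
        ids = self.ids
        runs: List[List[int]] = []
        for i in ids:
            if runs and i == runs[-1][-1] + 1:
                runs[-1].append(i)
            else:
                runs.append([i])
        return ",".join(
            f"{r[0]}-{r[-1]}" if len(r) > 2 else ",".join(map(str, r))
            for r in runs
        )


@dataclass(frozen=True)
class GAConfig:
    population_size: int = 24
    generations: int = 30
    crossover_prob: float = 0.8
    mutation_prob: float = 0.02
    elitism_count: int = 2
    tournament_size: int = 2
    n_repeats: int = 2
    n_channels: int = 22
    init_density: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.population_size % 2:
            raise ValueError("population size must be even")
        for p in (self.crossover_prob, self.mutation_prob, self.init_density):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0,1]")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")


@dataclass
class GAHistory:
    """Per-generation best and mean fitness for each repeat."""

    best: List[List[float]] = field(default_factory=list)
    mean: List[List[float]] = field(default_factory=list)
    best_per_repeat: List[Tuple[ChannelMask, float]] = field(default_factory=list)


def _repair(bits: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    if bits.sum() == 0:
        bits[rng.integers(len(bits))] = 1
    return bits


def ga_select(fitness: Callable[[ChannelMask], float],
              config: GAConfig) -> Tuple[ChannelMask, GAHistory]:
    """Best-of-repeats genetic search; deterministic for a fixed seed.

    ``fitness`` must accept any mask with popcount >= 1.  Evaluations are
    cached by mask key so duplicated individuals are not re-scored.
    """
    cache: Dict[Tuple[int, ...], float] = {}

    def score(bits: np.ndarray) -> float:
        key = tuple(int(b) for b in bits)
        if key not in cache:
            cache[key] = float(fitness(ChannelMask(key)))
        return cache[key]

    history = GAHistory()
    overall: Tuple[float, Tuple[int, ...]] | None = None
    for rep in range(config.n_repeats):
        rng = np.random.Generator(np.random.PCG64([config.seed, rep]))
        pop = (rng.random((config.population_size, config.n_channels))
               < config.init_density).astype(np.int8)
        for row in pop:
            _repair(row, rng)
        rep_best: Tuple[float, Tuple[int, ...]] | None = None
        gen_best, gen_mean = [], []
        for _ in range(config.generations):
            fits = np.array([score(row) for row in pop])
            order = np.argsort(-fits, kind="stable")
            if rep_best is None or fits[order[0]] > rep_best[0]:
                rep_best = (float(fits[order[0]]),
                            tuple(int(b) for b in pop[order[0]]))
            gen_best.append(float(fits[order[0]]))
            gen_mean.append(float(fits.mean()))
            elite = pop[order[: config.elitism_count]].copy()
            children = [row.copy() for row in elite]
            while len(children) < config.population_size:
                parents = []
                for _ in range(2):
                    cand = rng.integers(0, config.population_size,
                                        size=config.tournament_size)
                    parents.append(pop[cand[np.argmax(fits[cand])]].copy())
                if rng.random() < config.crossover_prob:
                    swap = rng.random(config.n_channels) < 0.5
                    parents[0][swap], parents[1][swap] = (
                        parents[1][swap].copy(), parents[0][swap].copy())
                for child in parents:
                    flip = rng.random(config.n_channels) < config.mutation_prob
                    child[flip] ^= 1
                    children.append(_repair(child, rng))
            pop = np.stack(children[: config.population_size])
        # score the final generation too
        fits = np.array([score(row) for row in pop])
        i = int(np.argmax(fits))
        if fits[i] > rep_best[0]:
            rep_best = (float(fits[i]), tuple(int(b) for b in pop[i]))
        history.best.append(gen_best)
        history.mean.append(gen_mean)
        history.best_per_repeat.append((ChannelMask(rep_best[1]), rep_best[0]))
        if overall is None or rep_best[0] > overall[0]:
            overall = rep_best
    return ChannelMask(overall[1]), history


def fitness_cross_subject(
    mask: ChannelMask,
    source_cohort: Cohort,
    test_subject: int,
    variant: ModelVariant,
    train_cfg: TrainConfig,
) -> float:
    """Accuracy on the held-out source subject using only masked channels."""
    if mask.popcount < 1:
        raise ValueError("mask selects no channels")
    if test_subject not in source_cohort.subject_ids:
        raise ValueError(f"subject {test_subject} not in the source cohort")
    train_sets = [
        drop_channels(source_cohort.combined(sid), mask)
        for sid in source_cohort.subject_ids
        if sid != test_subject
    ]
    train_data = TrialSet.concatenate(train_sets)
    test_data = drop_channels(source_cohort.combined(test_subject), mask)
    model = build_model(variant, train_data.n_channels, train_data.n_samples,
                        seed=train_cfg.seed)
    train(model, train_data, train_cfg)
    labels, _ = predict(model, test_data)
    return float((labels == test_data.labels).mean())
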