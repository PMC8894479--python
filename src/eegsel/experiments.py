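"""Desk-scale experiment recipes: end-to-end channel recovery and null checks.

These functions bundle the full pipeline — synthetic subject, preprocessing,
splitting, CNN evaluator, NSGA-II — into seeded, reproducible experiments at
a problem size a single CPU core handles in about a minute per run: an
8-channel montage subset, 20 trials of 60 s, 2-s segments, the tiny CNN
profile (F1=4, D=2, F2=8, 8 epochs), populations of 10 and at most 12
generations.

The recovery conditions plant three *complementary* informative channels
(each expressing trial carries the cue on one of them per time block), so a
selection run must identify the full planted set to saturate accuracy; see
:mod:`eegsel.synthetic`.  Splits are grouped by trial so sibling segments of
one trial never straddle train and test.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .dataio import ChannelMontage, DEAP_MONTAGE_32
from .nn import CNNConfig, build_model, evaluate, train
from .preprocess import SplitSpec, balance, label_trials, segment, split
from .selection import CNNMaskEvaluator, ParetoFront, evolve
from .synthetic import SyntheticSpec, generate_subject

RECOVERY_MONTAGE = ChannelMontage(DEAP_MONTAGE_32[:8])
PLANTED_AROUSAL = ("F3", "C3", "T7")
PLANTED_VALENCE = ("Fp1", "FC1", "AF3")


def recovery_spec(seed: int, effect_size: float = 4.0) -> SyntheticSpec:
    """Study conditions for one planted-channel recovery subject."""
    return SyntheticSpec(
        n_trials=20, trial_seconds=60.0, montage=RECOVERY_MONTAGE,
        arousal_channels=PLANTED_AROUSAL, valence_channels=PLANTED_VALENCE,
        effect_size=effect_size, complementary=True,
        high_rating_range=(6.5, 8.5),
        class_counts={"arousal": (10, 10), "valence": (10, 10)}, seed=seed)


def tiny_cnn_config() -> CNNConfig:
    return CNNConfig.tiny(epochs=8)


def _segments(spec: SyntheticSpec, seed: int, dimension: str = "arousal",
              seg_seconds: float = 2.0):
    rec, ratings, truth = generate_subject(spec, seed=seed)
    labels = label_trials(ratings, dimension)
    retained = balance(labels, seed=seed)
    return segment(rec, retained, labels, seg_seconds, dimension), truth


@dataclass
class RecoveryResult:
    """Outcome of one seeded recovery run."""

    front: ParetoFront
    planted: tuple[str, ...]
    selected_size3: tuple[str, ...]
    n_planted_recovered: int
    n_evaluations: int


def recovery_run(seed: int, pop_size: int = 10, max_gen: int = 12) -> RecoveryResult:
    """One full NSGA-II channel-selection run against known planted channels.

    Returns the archive Pareto front plus how many of the three planted
    channels appear in its size-3 entry (0 if the front has no size-3 entry).
    """
    spec = recovery_spec(seed)
    ds, truth = _segments(spec, seed)
    cfg = tiny_cnn_config()
    evaluator = CNNMaskEvaluator(ds, cfg, seed=seed,
                                 split_spec=SplitSpec(seed=seed, grouping="trial"))
    front, _ = evolve(evaluator, n_genes=len(spec.montage),
                      pop_size=pop_size, max_gen=max_gen, seed=seed)
    entries3 = [e for e in front.entries if e.n_channels == 3]
    selected = entries3[0].channel_labels(spec.montage) if entries3 else ()
    hits = len(set(selected) & set(truth.arousal_channels))
    return RecoveryResult(front, truth.arousal_channels, tuple(selected),
                          hits, evaluator.n_evaluations)


def null_accuracy(seed: int) -> float:
    """CNN test accuracy on an effect-free subject (must sit at chance).

    With ``effect_size = 0`` no channel carries class information, so the
    trained network's test accuracy estimates the chance level for two
    balanced classes.
    """
    spec = replace(recovery_spec(seed), effect_size=0.0, complementary=False)
    ds, _ = _segments(spec, seed)
    tr, va, te = split(ds, SplitSpec(seed=seed, grouping="trial"))
    cfg = tiny_cnn_config()
    model = build_model(ds.n_channels, ds.n_samples, cfg, seed=seed)
    train(model, tr, va, cfg, seed=seed)
    return evaluate(model, te)


def recovery_rate(seeds, min_hits: int = 2) -> tuple[float, list[RecoveryResult]]:
    """Fraction of seeded runs whose size-3 front entry has >= min_hits planted."""
    results = [recovery_run(s) for s in seeds]
    rate = float(np.mean([r.n_planted_recovered >= min_hits for r in results]))
    return rate, results
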