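"""Two-objective evolutionary EEG channel selection (NSGA-II).

A chromosome is a binary mask with one gene per montage channel (gene i = 1
means channel i is fed to the classifier).  Fitness is the pair
``(Acc, No)``: test accuracy of a network trained on exactly the masked
channels (maximized) and the number of selected channels (minimized).  The
search is a standard elitist NSGA-II: non-dominated sorting, crowding-distance
niching, binary tournament selection, uniform crossover, per-gene bit-flip
mutation, and (mu + lambda) survival.  Populations of 10 chromosomes evolve
until the objective-space movement over a 10-generation window drops below a
tolerance (checked at every 10th generation) or a generation cap is reached.

Evaluations are cached by gene mask, so an identical mask is never retrained;
with a seeded evaluator the fitness is a deterministic function of the mask
and the whole run is reproducible.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .dataio import ChannelMontage
from .nn import CNNConfig, train_eval_masked
from .preprocess import SegmentDataset, SplitSpec, split

Evaluator = Callable[[np.ndarray], float]  # mask -> accuracy in [0, 1]


@dataclass(frozen=True)
class Fitness:
    """(Acc, No): accuracy to maximize, channel count to minimize."""

    acc: float
    n_channels: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.acc <= 1.0):
            raise ValueError("accuracy must lie in [0, 1]")
        if self.n_channels < 1:
            raise ValueError("a chromosome must select at least one channel")


def dominates(a: Fitness, b: Fitness) -> bool:
    """True iff a is at least as good in both objectives and better in one."""
    ge = a.acc >= b.acc and a.n_channels <= b.n_channels
    strict = a.acc > b.acc or a.n_channels < b.n_channels
    return ge and strict


def non_dominated_sort(points: Sequence[Fitness]) -> list[list[int]]:
    """Fast non-dominated sorting; returns index lists, front 0 first."""
    n = len(points)
    if n == 0:
        raise ValueError("no points to sort")
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    n_dominating = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if dominates(points[i], points[j]):
                dominated_by[i].append(j)
                n_dominating[j] += 1
            elif dominates(points[j], points[i]):
                dominated_by[j].append(i)
                n_dominating[i] += 1
    fronts: list[list[int]] = []
    current = [i for i in range(n) if n_dominating[i] == 0]
    while current:
        fronts.append(current)
        nxt: list[int] = []
        for i in current:
            for j in dominated_by[i]:
                n_dominating[j] -= 1
                if n_dominating[j] == 0:
                    nxt.append(j)
        current = nxt
    return fronts


def crowding_distance(front: Sequence[Fitness]) -> np.ndarray:
    """NSGA-II crowding distance; boundary points get +inf.

    Interior points receive, per objective, the normalized gap between their
    two neighbors along that objective, summed over objectives.
    """
    n = len(front)
    if n == 0:
        raise ValueError("empty front")
    dist = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for key in (lambda f: f.acc, lambda f: f.n_channels):
        vals = np.array([key(f) for f in front], dtype=float)
        order = np.argsort(vals, kind="stable")
        vmin, vmax = vals[order[0]], vals[order[-1]]
        dist[order[0]] = dist[order[-1]] = np.inf
        if vmax > vmin:
            for r in range(1, n - 1):
                dist[order[r]] += (vals[order[r + 1]] - vals[order[r - 1]]) / (vmax - vmin)
    return dist


# ---------------------------------------------------------------------------
# chromosome evaluation
# ---------------------------------------------------------------------------

def repair(mask: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Flip one uniformly random gene on if the mask selects no channel."""
    mask = np.asarray(mask, dtype=np.int8).copy()
    if mask.sum() == 0:
        mask[rng.integers(len(mask))] = 1
    return mask


def evaluate_chromosome(mask: np.ndarray, evaluator: Evaluator,
                        cache: dict[bytes, Fitness] | None = None) -> Fitness:
    """Fitness of one mask; identical masks are served from the cache."""
    mask = np.asarray(mask, dtype=np.int8)
    if mask.sum() == 0:
        raise ValueError("all-zero chromosome must be repaired before evaluation")
    key = mask.tobytes()
    if cache is not None and key in cache:
        return cache[key]
    fit = Fitness(float(evaluator(mask)), int(mask.sum()))
    if cache is not None:
        cache[key] = fit
    return fit


class CNNMaskEvaluator:
    """Trains the compact CNN on the masked channels of one subject's data.

    Data is split 50/25/25 once (so every chromosome sees the same partition)
    and the returned accuracy is the test-set accuracy of the
    best-validation-epoch checkpoint.  The training seed is fixed, making the
    fitness a deterministic function of the mask.
    """

    def __init__(self, ds: SegmentDataset, cfg: CNNConfig, seed: int = 0,
                 split_spec: SplitSpec | None = None):
        self.cfg = cfg
        self.seed = seed
        spec = split_spec or SplitSpec(seed=seed)
        self.train_set, self.val_set, self.test_set = split(ds, spec)
        self.n_evaluations = 0

    def __call__(self, mask: np.ndarray) -> float:
        self.n_evaluations += 1
        return train_eval_masked(self.train_set, self.val_set, self.test_set,
                                 np.asarray(mask, dtype=bool), self.cfg, seed=self.seed)


# ---------------------------------------------------------------------------
# Pareto front containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ParetoEntry:
    mask: tuple[int, ...]
    acc: float
    n_channels: int

    @property
    def fitness(self) -> Fitness:
        return Fitness(self.acc, self.n_channels)

    def channel_labels(self, montage: ChannelMontage) -> tuple[str, ...]:
        return tuple(montage.names[i] for i, g in enumerate(self.mask) if g)


@dataclass
class ParetoFront:
    """Mutually non-dominated (mask, Acc, No) set, sorted by channel count."""

    entries: list[ParetoEntry] = field(default_factory=list)

    def __post_init__(self) -> None:
        for a, b in itertools.permutations(self.entries, 2):
            if dominates(a.fitness, b.fitness):
                raise ValueError("Pareto front contains a dominated entry")
        self.entries.sort(key=lambda e: (e.n_channels, -e.acc))

    def __len__(self) -> int:
        return len(self.entries)

    @staticmethod
    def from_evaluated(items: Iterable[tuple[np.ndarray, Fitness]]) -> "ParetoFront":
        """Non-dominated filter keeping one representative per (Acc, No) point."""
        pool = [(np.asarray(m, dtype=np.int8), f) for m, f in items]
        fits = [f for _, f in pool]
        keep: list[ParetoEntry] = []
        seen: set[tuple[float, int]] = set()
        for i, (m, f) in enumerate(pool):
            if any(dominates(g, f) for g in fits):
                continue
            pt = (f.acc, f.n_channels)
            if pt in seen:
                continue
            seen.add(pt)
            keep.append(ParetoEntry(tuple(int(v) for v in m), f.acc, f.n_channels))
        return ParetoFront(keep)

    def points(self) -> list[Fitness]:
        return [e.fitness for e in self.entries]


def brute_force_pareto(evaluator: Evaluator, n_channels: int,
                       max_channels: int = 12) -> ParetoFront:
    """Exact Pareto front by exhaustive enumeration of all 2^n - 1 masks."""
    if n_channels > max_channels:
        raise ValueError(f"{n_channels} channels: 2^n enumeration refused (max {max_channels})")
    items = []
    for bits in range(1, 2 ** n_channels):
        mask = np.array([(bits >> i) & 1 for i in range(n_channels)], dtype=np.int8)
        items.append((mask, Fitness(float(evaluator(mask)), int(mask.sum()))))
    return ParetoFront.from_evaluated(items)


# ---------------------------------------------------------------------------
# the NSGA-II loop
# ---------------------------------------------------------------------------

@dataclass
class EvolveHistory:
    """Per-generation record of population fitnesses and archive-front extremes."""

    generations: list[list[Fitness]] = field(default_factory=list)
    ideal: list[tuple[float, int]] = field(default_factory=list)
    nadir: list[tuple[float, int]] = field(default_factory=list)
    stopped_at: int = 0
    termination: str = "max_gen"


def _front_extremes(front: ParetoFront) -> tuple[tuple[float, int], tuple[float, int]]:
    accs = [e.acc for e in front.entries]
    nos = [e.n_channels for e in front.entries]
    return (max(accs), min(nos)), (min(accs), max(nos))


def _tournament(rng, ranks, crowd):
    i, j = rng.integers(len(ranks)), rng.integers(len(ranks))
    if ranks[i] < ranks[j]:
        return i
    if ranks[j] < ranks[i]:
        return j
    return i if crowd[i] >= crowd[j] else j


def _rank_and_crowd(fits: list[Fitness]) -> tuple[np.ndarray, np.ndarray]:
    fronts = non_dominated_sort(fits)
    ranks = np.empty(len(fits), dtype=int)
    crowd = np.empty(len(fits))
    for r, fr in enumerate(fronts):
        ranks[fr] = r
        crowd[fr] = crowding_distance([fits[i] for i in fr])
    return ranks, crowd


def evolve(evaluator: Evaluator, n_genes: int, pop_size: int = 10,
           max_gen: int = 100, tol: float = 0.001, seed: int = 0,
           p_crossover: float = 0.9, p_mutation: float | None = None,
           check_every: int = 10,
           cache: dict[bytes, Fitness] | None = None) -> tuple[ParetoFront, EvolveHistory]:
    """Elitist NSGA-II over binary channel masks.

    Stops early when the normalized movement of the archive front's ideal and
    nadir points over the last ``check_every`` generations is below ``tol``
    (evaluated at generations 10, 20, ...), else at ``max_gen``.  Returns the
    Pareto front over *all* evaluated chromosomes plus the run history.
    """
    if max_gen < 1:
        raise ValueError("max_gen must be >= 1")
    if pop_size < 2:
        raise ValueError("population size must be >= 2")
    if p_mutation is None:
        p_mutation = 1.0 / n_genes
    rng = np.random.default_rng(seed)
    cache = cache if cache is not None else {}
    archive: dict[bytes, tuple[np.ndarray, Fitness]] = {}

    def fitness_of(mask: np.ndarray) -> Fitness:
        fit = evaluate_chromosome(mask, evaluator, cache)
        archive.setdefault(mask.tobytes(), (mask.copy(), fit))
        return fit

    pop = [repair((rng.random(n_genes) < 0.5).astype(np.int8), rng) for _ in range(pop_size)]
    fits = [fitness_of(m) for m in pop]
    history = EvolveHistory()
    history.generations.append(list(fits))
    extremes_log: list[tuple[tuple[float, int], tuple[float, int]]] = []
    front = ParetoFront.from_evaluated(archive.values())
    extremes_log.append(_front_extremes(front))

    for gen in range(1, max_gen + 1):
        ranks, crowd = _rank_and_crowd(fits)
        offspring: list[np.ndarray] = []
        while len(offspring) < pop_size:
            pa = pop[_tournament(rng, ranks, crowd)]
            pb = pop[_tournament(rng, ranks, crowd)]
            if rng.random() < p_crossover:
                swap = rng.random(n_genes) < 0.5
                ca = np.where(swap, pb, pa)
                cb = np.where(swap, pa, pb)
            else:
                ca, cb = pa.copy(), pb.copy()
            for child in (ca, cb):
                flips = rng.random(n_genes) < p_mutation
                child = np.where(flips, 1 - child, child).astype(np.int8)
                offspring.append(repair(child, rng))
        offspring = offspring[:pop_size]
        off_fits = [fitness_of(m) for m in offspring]
        # (mu + lambda) survival by rank then crowding
        combined = pop + offspring
        comb_fits = fits + off_fits
        ranks, crowd = _rank_and_crowd(comb_fits)
        order = sorted(range(len(combined)), key=lambda i: (ranks[i], -crowd[i]))
        keep = order[:pop_size]
        pop = [combined[i] for i in keep]
        fits = [comb_fits[i] for i in keep]
        history.generations.append(list(fits))
        front = ParetoFront.from_evaluated(archive.values())
        extremes_log.append(_front_extremes(front))
        history.stopped_at = gen
        if gen % check_every == 0 and gen >= check_every:
            (i_now, n_now), (i_old, n_old) = extremes_log[-1], extremes_log[-1 - check_every]
            moves = [abs(i_now[0] - i_old[0]),              # accuracy already in [0, 1]
                     abs(i_now[1] - i_old[1]) / n_genes,
                     abs(n_now[0] - n_old[0]),
                     abs(n_now[1] - n_old[1]) / n_genes]
            if max(moves) < tol:
                history.termination = "tolerance"
                break

    history.ideal = [e[0] for e in extremes_log]
    history.nadir = [e[1] for e in extremes_log]
    front = ParetoFront.from_evaluated(archive.values())
    return front, history


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------

def per_size_best(front: ParetoFront, sizes: Sequence[int] = tuple(range(1, 16))) -> dict[int, float | None]:
    """Best accuracy per channel count; None where the front has no entry."""
    out: dict[int, float | None] = {s: None for s in sizes}
    for e in front.entries:
        if e.n_channels in out:
            best = out[e.n_channels]
            out[e.n_channels] = e.acc if best is None else max(best, e.acc)
    return out


def coincidence_tally(fronts: Mapping[tuple[str, str], ParetoFront],
                      montage: ChannelMontage,
                      sizes: Sequence[int] = tuple(range(1, 16))) -> pd.DataFrame:
    """Cross-subject channel-usage counts per Pareto-front size.

    ``fronts`` maps (subject, dimension) to that run's Pareto front; pooling
    both dimensions doubles the maximum possible count per subject.  Returns
    a (size x channel) table of how many (subject, dimension) front entries of
    that size used each channel.
    """
    if not fronts:
        raise ValueError("no fronts to tally")
    counts = pd.DataFrame(0, index=list(sizes), columns=list(montage.names))
    for front in fronts.values():
        for s in sizes:
            entries = [e for e in front.entries if e.n_channels == s]
            if not entries:
                continue
            best = max(entries, key=lambda e: e.acc)
            for ch in best.channel_labels(montage):
                counts.loc[s, ch] += 1
    counts.index.name = "front_size"
    return counts
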