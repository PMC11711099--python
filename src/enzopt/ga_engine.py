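"""The evolutionary loop: evaluate, select, cross over, mutate, iterate.

The engine evolves a fixed-size population of fixed-length mutants of one
wild-type enzyme.  Defaults follow the published protocol the toolkit
emulates: population 500, 30 generations, top-80% truncation selection.
Each generation the survivors are carried over and the remaining slots are
refilled by single-point crossover of survivor pairs followed by a fresh
round of strategy-proposed mutations; the single best member is always
carried unmodified (elitism), so the best-score trajectory is monotone
non-decreasing.

The maximum-mutation constraint is enforced against the *original wild
type*, not the immediate parent: reported mutants are characterised by
their distance to WT, and crossover of two in-budget parents can otherwise
drift arbitrarily far.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np

from .core_sequences import (
    MutantRecord,
    ProteinSequence,
    make_mutant_record,
    mutations_between,
)
from .mutation_strategies import StrategyConfig, propose_mutants

#: A fitness function maps a residue string to a finite float (higher is better).
FitnessFn = Callable[[str], float]

#: Key under which the primary fitness score is stored on each member.
FITNESS_KEY = "fitness"


@dataclass(frozen=True)
class GAConfig:
    """Genetic-algorithm hyperparameters.

    ``retain_fraction`` is the truncation-selection survivor fraction;
    survivor count is ``ceil(retain_fraction * population_size)``.
    ``crossover_rate`` is the probability that a refill slot is produced by
    crossover of two distinct survivors rather than a survivor copy.
    ``crossover_kind`` selects single-point (default) or uniform crossover.
    ``stop_on_score`` stops the run early once the best score reaches it.
    """

    population_size: int = 500
    generations: int = 30
    retain_fraction: float = 0.8
    crossover_rate: float = 0.8
    crossover_kind: str = "single_point"
    strategy_config: StrategyConfig = field(default_factory=StrategyConfig)
    seed: int = 0
    stop_on_score: float | None = None

    def __post_init__(self) -> None:
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.generations < 1:
            raise ValueError("generations must be >= 1")
        if not 0.0 < self.retain_fraction <= 1.0:
            raise ValueError("retain_fraction must be in (0, 1]")
        if not 0.0 <= self.crossover_rate <= 1.0:
            raise ValueError("crossover_rate must be in [0, 1]")
        if self.crossover_kind not in ("single_point", "uniform"):
            raise ValueError("crossover_kind must be 'single_point' or 'uniform'")


@dataclass
class Population:
    """One generation: an index plus its scored members."""

    generation_index: int
    members: list[MutantRecord]

    def __post_init__(self) -> None:
        lengths = {len(m.sequence) for m in self.members}
        if len(lengths) > 1:
            raise ValueError(f"population members have mixed lengths {sorted(lengths)}")

    def scores(self) -> list[float]:
        return [m.scores[FITNESS_KEY] for m in self.members]

    def best(self) -> MutantRecord:
        return min(
            self.members,
            key=lambda m: (-m.scores[FITNESS_KEY], m.sequence.residues),
        )


@dataclass
class OptimizationResult:
    """Outcome of one GA run.

    ``best_score_per_generation`` includes the initial population as
    generation 1; elitism makes it non-decreasing.  ``first_hit_iteration``
    is the 1-based index of the first generation attaining the trajectory
    maximum.
    """

    best: MutantRecord
    best_score_per_generation: list[float]
    first_hit_iteration: int
    config: GAConfig
    seed: int


def evaluate(pop: Population, fitness: FitnessFn) -> Population:
    """Attach a fitness score to every member (idempotent for scored members).

    Members whose fitness raises or returns a non-finite value are dropped
    with a warning rather than poisoning selection.
    """
    kept: list[MutantRecord] = []
    for m in pop.members:
        if FITNESS_KEY in m.scores:
            kept.append(m)
            continue
        try:
            score = float(fitness(m.sequence.residues))
        except Exception as exc:  # noqa: BLE001 - contract: discard and warn
            warnings.warn(
                f"fitness failed for {m.sequence.id!r} ({exc}); member discarded",
                stacklevel=2,
            )
            continue
        if not math.isfinite(score):
            warnings.warn(
                f"non-finite fitness {score!r} for {m.sequence.id!r}; member discarded",
                stacklevel=2,
            )
            continue
        m.scores[FITNESS_KEY] = score
        kept.append(m)
    return Population(generation_index=pop.generation_index, members=kept)


def select_top_fraction(pop: Population, fraction: float) -> Population:
    """Keep the ``ceil(fraction * n)`` highest-scoring members.

    Ties are broken by ascending sequence string so selection is
    deterministic across platforms.
    """
    if not pop.members:
        raise ValueError("cannot select from an empty population")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    n_keep = math.ceil(fraction * len(pop.members))
    ranked = sorted(
        pop.members, key=lambda m: (-m.scores[FITNESS_KEY], m.sequence.residues)
    )
    return Population(generation_index=pop.generation_index, members=ranked[:n_keep])


def crossover(
    a: ProteinSequence,
    b: ProteinSequence,
    rng: np.random.Generator,
    kind: str = "single_point",
) -> ProteinSequence:
    """Recombine two equal-length parents into a child sequence.

    Single-point: cut point ``c`` uniform in ``1..L-1``; child is
    ``a[1..c] + b[c+1..L]``.  Uniform: each position drawn from either
    parent with probability 1/2.
    """
    if len(a) != len(b):
        raise ValueError(f"crossover length mismatch: {len(a)} vs {len(b)}")
    L = len(a)
    if L < 2:
        raise ValueError("crossover needs sequences of length >= 2")
    if kind == "single_point":
        c = int(rng.integers(1, L))
        residues = a.residues[:c] + b.residues[c:]
    elif kind == "uniform":
        mask = rng.integers(0, 2, size=L)
        residues = "".join(
            a.residues[i] if mask[i] == 0 else b.residues[i] for i in range(L)
        )
    else:
        raise ValueError(f"unknown crossover kind {kind!r}")
    return ProteinSequence(id=f"x({a.id},{b.id})", residues=residues)


def _constrain_to_wild_type(
    wild_type: ProteinSequence,
    child: ProteinSequence,
    max_mutations: int,
    rng: np.random.Generator,
) -> ProteinSequence:
    """Revert randomly chosen excess substitutions until within budget."""
    diffs = mutations_between(wild_type, child)
    if len(diffs) <= max_mutations:
        return child
    keep_idx = rng.choice(len(diffs), size=max_mutations, replace=False)
    kept = [diffs[i] for i in sorted(int(i) for i in keep_idx)]
    from .core_sequences import apply_mutations

    return apply_mutations(wild_type, kept)


def step(
    pop: Population,
    fitness: FitnessFn,
    cfg: GAConfig,
    backend,
    rng: np.random.Generator,
    wild_type: ProteinSequence,
) -> Population:
    """Produce the next generation of exactly ``cfg.population_size`` members.

    Survivors (top fraction) carry over unchanged; each remaining slot is
    filled by crossover of two distinct survivors (with probability
    ``crossover_rate``) or a survivor copy, then passed through the mutation
    strategy, then clipped back to the wild-type mutation budget.
    """
    survivors = select_top_fraction(pop, cfg.retain_fraction)
    members: list[MutantRecord] = list(survivors.members)
    n_new = cfg.population_size - len(members)
    scfg = cfg.strategy_config
    for _ in range(n_new):
        if len(survivors.members) >= 2 and rng.random() < cfg.crossover_rate:
            i, j = rng.choice(len(survivors.members), size=2, replace=False)
            base = crossover(
                survivors.members[int(i)].sequence,
                survivors.members[int(j)].sequence,
                rng,
                cfg.crossover_kind,
            )
        else:
            i = int(rng.integers(len(survivors.members)))
            base = survivors.members[i].sequence
        proposed = propose_mutants(base, scfg, backend, 1, rng)
        child = proposed[0].sequence if proposed else base
        child = _constrain_to_wild_type(wild_type, child, scfg.max_mutations, rng)
        members.append(make_mutant_record(wild_type, child))
    nxt = Population(generation_index=pop.generation_index + 1, members=members)
    return evaluate(nxt, fitness)


def first_hit_iteration(best_score_per_generation: Sequence[float]) -> int:
    """1-based index of the first generation attaining the trajectory maximum."""
    if len(best_score_per_generation) == 0:
        raise ValueError("empty trajectory")
    arr = np.asarray(best_score_per_generation, dtype=float)
    return int(np.argmax(arr)) + 1


def run(
    wild_type: ProteinSequence,
    fitness: FitnessFn,
    cfg: GAConfig,
    backend,
) -> OptimizationResult:
    """Run the full GA from a wild type; fully reproducible per ``cfg.seed``.

    The initial population (generation 1) is the wild type plus
    ``population_size - 1`` strategy-proposed mutants.  Iteration stops after
    ``cfg.generations`` generations or as soon as ``stop_on_score`` is
    reached.
    """
    rng = np.random.default_rng(cfg.seed)
    members = [make_mutant_record(wild_type, wild_type)]
    proposed = propose_mutants(
        wild_type, cfg.strategy_config, backend, cfg.population_size - 1, rng
    )
    members.extend(proposed)
    while len(members) < cfg.population_size:  # exhausted neighborhoods: pad with WT
        members.append(make_mutant_record(wild_type, wild_type))
    pop = evaluate(Population(generation_index=1, members=members), fitness)

    trajectory = [pop.best().scores[FITNESS_KEY]]
    for _ in range(cfg.generations - 1):
        if cfg.stop_on_score is not None and trajectory[-1] >= cfg.stop_on_score:
            break
        pop = step(pop, fitness, cfg, backend, rng, wild_type)
        trajectory.append(pop.best().scores[FITNESS_KEY])

    return OptimizationResult(
        best=pop.best(),
        best_score_per_generation=trajectory,
        first_hit_iteration=first_hit_iteration(trajectory),
        config=cfg,
        seed=cfg.seed,
    )
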