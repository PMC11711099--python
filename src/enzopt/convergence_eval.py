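"""Convergence diagnostics for mutation-strategy comparison.

A run's *first-hit iteration* is the earliest generation at which its best
score reaches the run maximum.  An ideal strategy converges in a single
iteration, so each strategy's first-hit distribution is compared against a
point mass at iteration 1 via the first Wasserstein distance — against that
reference the distance reduces to mean(|x - 1|).  Strategies are compared
pairwise with a rank test on per-(reaction, seed) paired first hits
(Wilcoxon signed-rank when the grid is complete, rank-sum otherwise).

A scaled-down replication harness runs the full strategies x max-mutations
x seeds x reactions grid on synthetic target-match landscapes and emits the
comparison table.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu as _scipy_mwu
from scipy.stats import wasserstein_distance as _scipy_wasserstein
from scipy.stats import wilcoxon as _scipy_wilcoxon

from .ga_engine import GAConfig, first_hit_iteration, run
from .mutation_strategies import (
    StrategyConfig,
    TargetOraclePredictor,
    build_basic_matrix,
    build_smart_matrix,
)
from .synthetic_data import LandscapeSpec, make_landscape, make_msa

__all__ = [
    "RunSummary",
    "ReferenceDistribution",
    "first_hit_iteration",
    "wasserstein_1d",
    "compare_strategies",
    "run_strategy_grid",
    "read_run_summaries",
    "write_run_summaries",
]


@dataclass(frozen=True)
class RunSummary:
    """One GA run's convergence record on the experimental grid."""

    strategy: str
    max_mutations: int
    seed: int
    reaction_id: str
    first_hit_iteration: int

    def __post_init__(self) -> None:
        if self.first_hit_iteration < 1:
            raise ValueError("first_hit_iteration must be >= 1")


@dataclass(frozen=True)
class ReferenceDistribution:
    """Degenerate reference: all mass at the single-iteration optimum."""

    point: float = 1.0


def wasserstein_1d(
    samples: Sequence[float],
    reference: ReferenceDistribution | Sequence[float] = ReferenceDistribution(),
) -> float:
    """First Wasserstein distance between empirical distributions.

    Against the point-mass reference this equals mean(|x - point|); an
    arbitrary empirical reference is also accepted.
    """
    x = np.asarray(samples, dtype=float)
    if x.size == 0:
        raise ValueError("empty sample")
    if isinstance(reference, ReferenceDistribution):
        ref = np.asarray([reference.point])
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.size == 0:
            raise ValueError("empty reference sample")
    return float(_scipy_wasserstein(x, ref))


def compare_strategies(
    runs: Sequence[RunSummary],
    generation_budget: int,
    reference: ReferenceDistribution = ReferenceDistribution(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarise and compare first-hit distributions across strategies.

    Returns ``(distance_table, test_table)``:

    * ``distance_table`` — one row per (strategy, max_mutations) cell with
      its run count, mean first hit, and Wasserstein distance to the
      reference;
    * ``test_table`` — pairwise strategy comparisons per max_mutations
      level.  When both strategies cover the same complete (reaction, seed)
      grid the Wilcoxon signed-rank test on paired first hits is used,
      otherwise the Mann-Whitney rank-sum test; the choice is recorded in
      the ``test`` column.
    """
    if not runs:
        raise ValueError("no runs to compare")
    strategies = sorted({r.strategy for r in runs})
    if len(strategies) < 2:
        raise ValueError("need at least 2 strategies to compare")
    for r in runs:
        if r.first_hit_iteration > generation_budget + 1:
            raise ValueError(
                f"first hit {r.first_hit_iteration} exceeds censoring bound "
                f"{generation_budget + 1}"
            )
    df = pd.DataFrame([vars(r) for r in runs])

    dist_rows = []
    for (strategy, mm), cell in df.groupby(["strategy", "max_mutations"]):
        hits = cell["first_hit_iteration"].to_numpy(dtype=float)
        dist_rows.append(
            {
                "strategy": strategy,
                "max_mutations": mm,
                "n_runs": len(cell),
                "mean_first_hit": float(hits.mean()),
                "wasserstein_to_reference": wasserstein_1d(hits, reference),
            }
        )
    distance_table = pd.DataFrame(dist_rows).sort_values(
        ["max_mutations", "wasserstein_to_reference"], ignore_index=True
    )

    test_rows = []
    for mm, level in df.groupby("max_mutations"):
        for sa, sb in itertools.combinations(strategies, 2):
            a = level[level["strategy"] == sa]
            b = level[level["strategy"] == sb]
            if a.empty or b.empty:
                warnings.warn(
                    f"missing cell for {sa!r} or {sb!r} at max_mutations={mm}; skipped",
                    stacklevel=2,
                )
                continue
            key = ["reaction_id", "seed"]
            a_idx = a.set_index(key)["first_hit_iteration"]
            b_idx = b.set_index(key)["first_hit_iteration"]
            paired = (
                len(a_idx) == len(b_idx)
                and a_idx.index.is_unique
                and b_idx.index.is_unique
                and a_idx.index.sort_values().equals(b_idx.index.sort_values())
            )
            if paired:
                x = a_idx.sort_index().to_numpy(dtype=float)
                y = b_idx.sort_index().to_numpy(dtype=float)
                diffs = x - y
                if np.all(diffs == 0):
                    stat, p = 0.0, 1.0  # identical paired samples
                else:
                    stat, p = _scipy_wilcoxon(x, y)
                test_name = "wilcoxon-signed-rank"
            else:
                stat, p = _scipy_mwu(
                    a_idx.to_numpy(dtype=float),
                    b_idx.to_numpy(dtype=float),
                    alternative="two-sided",
                )
                test_name = "mann-whitney-rank-sum"
            test_rows.append(
                {
                    "max_mutations": mm,
                    "strategy_a": sa,
                    "strategy_b": sb,
                    "test": test_name,
                    "statistic": float(stat),
                    "p_value": float(p),
                }
            )
    test_table = pd.DataFrame(
        test_rows,
        columns=["max_mutations", "strategy_a", "strategy_b", "test", "statistic", "p_value"],
    )
    return distance_table, test_table


def pooled_strategy_distances(
    runs: Sequence[RunSummary],
    reference: ReferenceDistribution = ReferenceDistribution(),
) -> dict[str, float]:
    """Wasserstein distance to the reference per strategy, pooled over the grid."""
    if not runs:
        raise ValueError("no runs")
    out: dict[str, float] = {}
    for strategy in sorted({r.strategy for r in runs}):
        hits = [float(r.first_hit_iteration) for r in runs if r.strategy == strategy]
        out[strategy] = wasserstein_1d(hits, reference)
    return out


# --- scaled-down replication harness -----------------------------------------


@dataclass(frozen=True)
class GridSpec:
    """Experimental grid for the strategy-comparison harness.

    Defaults are a desk-scale version of the published comparison (which ran
    3 strategies x 3 max-mutation levels x 30 seeds x 27 reactions at 15
    cycles with population 100): same cycle count and population, fewer
    seeds and reactions.
    """

    strategies: tuple[str, ...] = ("llm", "smart", "basic")
    max_mutations_levels: tuple[int, ...] = (5, 10, 15)
    n_seeds: int = 5
    n_reactions: int = 3
    generations: int = 15
    population_size: int = 100
    sequence_length: int = 20
    wt_distance: int | None = None
    retain_fraction: float = 0.2
    llm_selection_mode: str = "argmax"
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.wt_distance is not None and self.wt_distance > min(
            self.max_mutations_levels
        ):
            raise ValueError(
                "wt_distance must not exceed the smallest max-mutations level, "
                "or the optimum is unreachable at that level"
            )


def run_strategy_grid(spec: GridSpec = GridSpec()) -> list[RunSummary]:
    """Run the full strategies x levels x seeds x reactions grid.

    Each "reaction" is a target-match landscape whose wild type is planted
    ``wt_distance`` substitutions from the hidden target (by default the
    cell's own max-mutations level, so every level poses a recovery problem
    that uses its full budget).  The informative (``llm``) strategy uses a
    target-oracle masked predictor, ``smart`` a transition matrix from an
    MSA of target homologs, and ``basic`` the uniform matrix.  Runs that
    never reach the landscape optimum within budget are censored at
    generations + 1.
    """
    from .synthetic_data import plant_mutations

    summaries: list[RunSummary] = []
    for reaction_idx in range(spec.n_reactions):
        landscape = make_landscape(
            LandscapeSpec(
                kind="target_match",
                length=spec.sequence_length,
                seed=spec.base_seed + 1000 + reaction_idx,
            )
        )
        target = landscape.target
        assert target is not None
        msa = make_msa(
            target, n_sequences=12, mutation_rate=0.15, seed=spec.base_seed + 3000 + reaction_idx
        )
        backends = {
            "llm": TargetOraclePredictor(target=target.residues),
            "smart": build_smart_matrix(msa),
            "basic": build_basic_matrix(),
        }
        for max_mut in spec.max_mutations_levels:
            level_budget = min(max_mut, spec.sequence_length)
            planted = spec.wt_distance if spec.wt_distance is not None else level_budget
            wild_type = plant_mutations(
                target,
                planted,
                spec.base_seed + 2000 + reaction_idx,
                id=f"reaction-{reaction_idx}-wt",
            )
            for strategy in spec.strategies:
                for seed_idx in range(spec.n_seeds):
                    seed = spec.base_seed + seed_idx
                    cfg = GAConfig(
                        population_size=spec.population_size,
                        generations=spec.generations,
                        retain_fraction=spec.retain_fraction,
                        strategy_config=StrategyConfig(
                            strategy=strategy,
                            max_mutations=level_budget,
                            seed=seed,
                            selection_mode=(
                                spec.llm_selection_mode if strategy == "llm" else "sample"
                            ),
                        ),
                        seed=seed,
                        stop_on_score=landscape.optimum_score,
                    )
                    result = run(wild_type, landscape, cfg, backends[strategy])
                    best_score = max(result.best_score_per_generation)
                    if best_score >= landscape.optimum_score:
                        hit = result.first_hit_iteration
                    else:
                        hit = spec.generations + 1  # censored: never converged
                    summaries.append(
                        RunSummary(
                            strategy=strategy,
                            max_mutations=max_mut,
                            seed=seed,
                            reaction_id=f"reaction-{reaction_idx}",
                            first_hit_iteration=hit,
                        )
                    )
    return summaries


# --- CSV I/O ------------------------------------------------------------------

RUN_COLUMNS = ["strategy", "max_mutations", "seed", "reaction_id", "first_hit_iteration"]


def write_run_summaries(runs: Sequence[RunSummary], path: str | Path) -> None:
    pd.DataFrame([vars(r) for r in runs], columns=RUN_COLUMNS).to_csv(path, index=False)


def read_run_summaries(path: str | Path) -> list[RunSummary]:
    df = pd.read_csv(path)
    missing = set(RUN_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"run summary table {path} missing columns {sorted(missing)}")
    return [
        RunSummary(
            strategy=str(row.strategy),
            max_mutations=int(row.max_mutations),
            seed=int(row.seed),
            reaction_id=str(row.reaction_id),
            first_hit_iteration=int(row.first_hit_iteration),
        )
        for row in df.itertuples()
    ]
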