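"""Candidate-mutation generation for the genetic algorithm.

Three interchangeable strategies propose substitutions at sampled positions
of a parent sequence:

``llm``
    A masked-predictor strategy: positions are masked and a predictor ranks
    replacement residues per position (the stand-in for a protein language
    model).  Any object satisfying :class:`MaskedPredictor` plugs in; the
    package ships deterministic synthetic predictors.
``smart``
    A 20x20 transition matrix estimated from residue co-occurrence in the
    columns of a multiple sequence alignment, so substitutions reflect
    conservation trends among homologs.
``basic``
    A uniform transition matrix (probability 1/19 to each other residue),
    the no-information control.

All strategies share one sampling path: choose how many positions to mutate
(uniform on 1..max_mutations), sample distinct positions in the editable
region, then draw a replacement residue per position from the strategy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .core_sequences import (
    AA_INDEX,
    AMINO_ACIDS,
    Mutation,
    MutantRecord,
    ProteinSequence,
    apply_mutations,
)

STRATEGIES = ("llm", "smart", "basic")


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 20x20 amino-acid substitution probabilities.

    Rows are "from" residues, columns "to" residues, both in the order of
    :data:`~enzopt.core_sequences.AMINO_ACIDS`.  The diagonal is zero:
    proposing a self-substitution would waste a fitness evaluation, since a
    mutant must differ from its parent.
    """

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.shape != (20, 20):
            raise ValueError(f"transition matrix must be 20x20, got {p.shape}")
        if (p < 0).any():
            raise ValueError("transition matrix entries must be non-negative")
        if not np.allclose(np.diag(p), 0.0):
            raise ValueError("transition matrix diagonal must be zero")
        if not np.allclose(p.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("every transition-matrix row must sum to 1")
        object.__setattr__(self, "probs", p)

    def row(self, residue: str) -> np.ndarray:
        return self.probs[AA_INDEX[residue]]

    def prob(self, from_residue: str, to_residue: str) -> float:
        return float(self.probs[AA_INDEX[from_residue], AA_INDEX[to_residue]])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.probs, index=list(AMINO_ACIDS), columns=list(AMINO_ACIDS)
        ).to_csv(path)

    @classmethod
    def from_csv(cls, path: str | Path) -> "TransitionMatrix":
        df = pd.read_csv(path, index_col=0)
        df = df.loc[list(AMINO_ACIDS), list(AMINO_ACIDS)]
        return cls(probs=df.to_numpy(dtype=float))


@runtime_checkable
class MaskedPredictor(Protocol):
    """Contract for masked-residue predictors.

    Given a residue string and a set of masked 1-based positions, return for
    each masked position a list of ``(residue, score)`` candidates sorted by
    decreasing score.  Implementations must be deterministic and return at
    least three candidates per position, all canonical letters.
    """

    def predict(
        self, residues: str, positions: Sequence[int]
    ) -> dict[int, list[tuple[str, float]]]: ...


@dataclass(frozen=True)
class TargetOraclePredictor:
    """Synthetic predictor that ranks a hidden target's residue first.

    At each masked position the target sequence's residue gets score 1;
    the remaining residues follow in alphabetical order with geometrically
    decaying scores.  Used to emulate an informative language model on
    landscapes whose optimum is known.
    """

    target: str

    def predict(
        self, residues: str, positions: Sequence[int]
    ) -> dict[int, list[tuple[str, float]]]:
        out: dict[int, list[tuple[str, float]]] = {}
        for pos in positions:
            best = self.target[pos - 1]
            ranked = [(best, 1.0)]
            score = 0.5
            for aa in AMINO_ACIDS:
                if aa != best:
                    ranked.append((aa, score))
                    score *= 0.9
            out[pos] = ranked
        return out


@dataclass(frozen=True)
class HashRankPredictor:
    """Deterministic no-signal predictor (plumbing tests, neutral baseline).

    Ranks residues by a hash of (sequence, position, salt): stable across
    calls and processes, carrying no information about fitness.
    """

    salt: int = 0

    def predict(
        self, residues: str, positions: Sequence[int]
    ) -> dict[int, list[tuple[str, float]]]:
        import hashlib

        out: dict[int, list[tuple[str, float]]] = {}
        for pos in positions:
            digest = hashlib.sha256(f"{self.salt}:{pos}:{residues}".encode()).digest()
            seed = int.from_bytes(digest[:4], "little")
            order = np.random.default_rng(seed).permutation(20)
            out[pos] = [
                (AMINO_ACIDS[j], 1.0 / (rank + 1)) for rank, j in enumerate(order)
            ]
        return out


@dataclass(frozen=True)
class StrategyConfig:
    """Configuration of one mutation strategy.

    ``editable_region`` is a 1-based inclusive ``(start, end)`` window inside
    which positions may be mutated; ``None`` means the whole sequence (no
    assumption is made about functional sites — callers that know active-site
    masks pass an explicit region).
    ``selection_mode`` controls how a residue is chosen among the predictor's
    top ``candidates_per_position``: ``"sample"`` draws uniformly from the
    pool, ``"argmax"`` always takes the top-ranked legal candidate.
    """

    strategy: str = "basic"
    max_mutations: int = 5
    editable_region: tuple[int, int] | None = None
    candidates_per_position: int = 3
    selection_mode: str = "sample"
    seed: int = 0
    max_retries: int = 50

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}; expected {STRATEGIES}")
        if self.max_mutations < 1:
            raise ValueError("max_mutations must be >= 1")
        if self.candidates_per_position < 1:
            raise ValueError("candidates_per_position must be >= 1")
        if self.selection_mode not in ("sample", "argmax"):
            raise ValueError("selection_mode must be 'sample' or 'argmax'")
        if self.editable_region is not None:
            start, end = self.editable_region
            if start < 1 or end < start:
                raise ValueError(f"invalid editable_region {self.editable_region}")

    def region_for(self, parent: ProteinSequence) -> tuple[int, int]:
        if self.editable_region is None:
            return (1, len(parent))
        start, end = self.editable_region
        if end > len(parent):
            raise ValueError(
                f"editable_region {self.editable_region} exceeds sequence "
                f"length {len(parent)}"
            )
        return (start, end)


def build_basic_matrix() -> TransitionMatrix:
    """Uniform substitution probabilities: 1/19 to every other residue."""
    p = np.full((20, 20), 1.0 / 19.0)
    np.fill_diagonal(p, 0.0)
    return TransitionMatrix(probs=p)


def build_smart_matrix(msa: Sequence[str | ProteinSequence]) -> TransitionMatrix:
    """Estimate a substitution matrix from column co-occurrence in an MSA.

    For each alignment column, every ordered pair of residues from two
    distinct sequences (gaps skipped) counts as one from→to event; identical
    pairs are discarded, since only actual substitutions are informative.
    Counts are pooled over columns and rows normalized.  A residue never seen
    substituting falls back to the uniform row, so the matrix stays usable
    for any parent sequence.
    """
    rows = [s.residues if isinstance(s, ProteinSequence) else s.upper() for s in msa]
    if not rows:
        raise ValueError("empty MSA")
    length = len(rows[0])
    if length == 0 or any(len(r) != length for r in rows):
        raise ValueError("MSA sequences must be non-empty and equal-length")
    if len(rows) < 2:
        raise ValueError("MSA must contain at least 2 sequences")

    counts = np.zeros((20, 20))
    for col in range(length):
        col_counts = np.zeros(20)
        for r in rows:
            aa = r[col]
            if aa in AA_INDEX:
                col_counts[AA_INDEX[aa]] += 1
        # ordered pairs across distinct sequences: n_a * n_b for a != b
        pair = np.outer(col_counts, col_counts)
        np.fill_diagonal(pair, 0.0)
        counts += pair

    basic_row = np.full(20, 1.0 / 19.0)
    probs = np.zeros((20, 20))
    for i in range(20):
        total = counts[i].sum()
        if total > 0:
            probs[i] = counts[i] / total
        else:
            probs[i] = basic_row
            probs[i, i] = 0.0
    np.fill_diagonal(probs, 0.0)
    # renormalize defensively (fallback rows already sum to 1)
    probs /= probs.sum(axis=1, keepdims=True)
    return TransitionMatrix(probs=probs)


def sample_positions(
    region: tuple[int, int], k: int, rng: np.random.Generator
) -> list[int]:
    """Sample ``k`` distinct 1-based positions uniformly inside ``region``."""
    start, end = region
    size = end - start + 1
    if k > size:
        raise ValueError(f"cannot sample {k} distinct positions from region of size {size}")
    picks = rng.choice(np.arange(start, end + 1), size=k, replace=False)
    return sorted(int(p) for p in picks)


def _draw_residue(
    parent_aa: str,
    position: int,
    parent: ProteinSequence,
    cfg: StrategyConfig,
    backend,
    rng: np.random.Generator,
    predictions: dict[int, list[tuple[str, float]]] | None,
) -> str:
    """One replacement residue at ``position``, never equal to the parent's."""
    if cfg.strategy == "llm":
        ranked = predictions[position]
        pool = [aa for aa, _ in ranked if aa != parent_aa][: cfg.candidates_per_position]
        if not pool:
            raise ValueError(
                f"predictor returned no legal candidate at position {position}"
            )
        if cfg.selection_mode == "argmax":
            return pool[0]
        return pool[int(rng.integers(len(pool)))]
    row = backend.row(parent_aa)
    return AMINO_ACIDS[int(rng.choice(20, p=row))]


def propose_mutants(
    parent: ProteinSequence,
    cfg: StrategyConfig,
    backend,
    n_offspring: int,
    rng: np.random.Generator | None = None,
) -> list[MutantRecord]:
    """Propose ``n_offspring`` distinct mutants of ``parent``.

    Each offspring carries between 1 and ``cfg.max_mutations`` substitutions
    at positions sampled without replacement inside the editable region.
    Offspring sequences are unique within the returned list; duplicates are
    resampled up to ``cfg.max_retries`` times, after which fewer offspring
    are returned with a warning (tiny neighborhoods can be exhausted).
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    region = cfg.region_for(parent)
    region_size = region[1] - region[0] + 1
    if cfg.max_mutations > region_size:
        raise ValueError(
            f"max_mutations={cfg.max_mutations} exceeds editable region size {region_size}"
        )
    if cfg.strategy == "llm" and not isinstance(backend, MaskedPredictor):
        raise TypeError("llm strategy requires a MaskedPredictor backend")
    if cfg.strategy in ("smart", "basic") and not isinstance(backend, TransitionMatrix):
        raise TypeError(f"{cfg.strategy} strategy requires a TransitionMatrix backend")

    out: list[MutantRecord] = []
    seen: set[str] = set()
    retries = 0
    while len(out) < n_offspring:
        k = int(rng.integers(1, cfg.max_mutations + 1))
        positions = sample_positions(region, k, rng)
        predictions = None
        if cfg.strategy == "llm":
            predictions = backend.predict(parent.residues, positions)
        mutations = []
        for pos in positions:
            parent_aa = parent[pos]
            new_aa = _draw_residue(parent_aa, pos, parent, cfg, backend, rng, predictions)
            mutations.append(Mutation(position=pos, wt_residue=parent_aa, new_residue=new_aa))
        child = apply_mutations(parent, mutations)
        if child.residues in seen:
            retries += 1
            if retries > cfg.max_retries:
                warnings.warn(
                    f"mutant neighborhood exhausted after {cfg.max_retries} retries; "
                    f"returning {len(out)} of {n_offspring} offspring",
                    stacklevel=2,
                )
                break
            continue
        seen.add(child.residues)
        out.append(
            MutantRecord(
                parent_id=parent.id,
                mutations=tuple(mutations),
                sequence=child,
            )
        )
    return out


def resolve_backend(
    cfg: StrategyConfig,
    *,
    predictor: MaskedPredictor | None = None,
    matrix: TransitionMatrix | None = None,
    msa: Sequence[str | ProteinSequence] | None = None,
):
    """Pick the backend object a strategy config needs.

    ``basic`` builds the uniform matrix; ``smart`` uses ``matrix`` or builds
    one from ``msa``; ``llm`` requires an explicit ``predictor``.
    """
    if cfg.strategy == "basic":
        return matrix if matrix is not None else build_basic_matrix()
    if cfg.strategy == "smart":
        if matrix is not None:
            return matrix
        if msa is None:
            raise ValueError("smart strategy needs a transition matrix or an MSA")
        return build_smart_matrix(msa)
    if predictor is None:
        raise ValueError("llm strategy needs a MaskedPredictor")
    return predictor
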