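"""Synthetic fixtures with known ground truth.

Every generator here is a pure function of its spec and seed, so tests and
the acceptance harness run without downloads and with analytic expectations:

* fitness landscapes with a known global optimum (GA recovery tests);
* labelled reaction datasets whose class separability has a closed-form
  Bayes ceiling (feasibility-model tests);
* kcat values with a known monotone dependence on latent coordinates
  (turnover-model tests);
* toy MSAs with controlled conservation (Smart-matrix tests);
* wild-type/mutant dihedral trajectory pairs with localized, time-windowed
  perturbations (MD-analytics tests).

The reaction generator draws a latent Gaussian vector per record and writes
placeholder molecule/protein strings; a lookup embedder reproduces the
latents deterministically from the stored strings.  Reported and random
classes sit at +/- delta/2 along a unit direction in latent space, so two
unit-variance Gaussian classes a distance delta apart give a Bayes AUC of
Phi(delta / sqrt(2)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Literal

import numpy as np

from .core_sequences import AMINO_ACIDS, ProteinSequence
from .fitness_models import ReactionRecord, TableEmbedder
from .md_analysis import DihedralTrajectory


def random_protein(length: int, seed: int | np.random.Generator, id: str = "synthetic") -> ProteinSequence:
    """Uniform i.i.d. residues over the 20-letter alphabet; reproducible per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = "".join(AMINO_ACIDS[i] for i in rng.integers(0, 20, size=length))
    return ProteinSequence(id=id, residues=residues)


def make_msa(
    ancestor: ProteinSequence,
    n_sequences: int,
    mutation_rate: float,
    seed: int,
    conserved_columns: dict[int, str] | None = None,
) -> list[str]:
    """Toy MSA: mutated copies of an ancestor with controlled conservation.

    ``conserved_columns`` maps 1-based columns to a string of letters the
    column is allowed to cycle through (e.g. ``{3: "AV"}`` makes column 3
    alternate A/V across sequences), planting a known substitution signal.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_sequences):
        residues = list(ancestor.residues)
        for i in range(len(residues)):
            if rng.random() < mutation_rate:
                residues[i] = AMINO_ACIDS[int(rng.integers(20))]
        if conserved_columns:
            for col, letters in conserved_columns.items():
                residues[col - 1] = letters[s % len(letters)]
        rows.append("".join(residues))
    return rows


# --- fitness landscapes ----------------------------------------------------

@dataclass(frozen=True)
class LandscapeSpec:
    """A scoring function with a closed-form global optimum.

    ``target_match`` scores the fraction of positions equal to a hidden
    target (optimum 1.0 at the target).  ``additive_site_weights`` scores the
    sum of per-site, per-residue weights (optimum = sum of column maxima).
    Optional Gaussian noise of sd ``noise_sd`` is added per evaluation.
    """

    kind: Literal["target_match", "additive_site_weights"] = "target_match"
    length: int = 12
    seed: int = 0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError("length must be >= 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass
class Landscape:
    """A callable fitness landscape plus its known optimum."""

    spec: LandscapeSpec
    fn: Callable[[str], float]
    optimum_score: float
    target: ProteinSequence | None = None
    weights: np.ndarray | None = None

    def __call__(self, residues: str) -> float:
        return self.fn(residues)


def make_landscape(spec: LandscapeSpec) -> Landscape:
    rng = np.random.default_rng(spec.seed)
    noise_rng = np.random.default_rng(spec.seed + 1)

    def noisy(x: float) -> float:
        if spec.noise_sd == 0:
            return x
        return x + float(noise_rng.normal(0.0, spec.noise_sd))

    if spec.kind == "target_match":
        target = random_protein(spec.length, rng, id="hidden-target")

        def fn(residues: str) -> float:
            if len(residues) != spec.length:
                raise ValueError("sequence length does not match landscape")
            match = sum(a == b for a, b in zip(residues, target.residues))
            return noisy(match / spec.length)

        return Landscape(spec=spec, fn=fn, optimum_score=1.0, target=target)

    weights = rng.uniform(0.0, 1.0, size=(spec.length, 20))
    aa_index = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

    def fn(residues: str) -> float:
        if len(residues) != spec.length:
            raise ValueError("sequence length does not match landscape")
        return noisy(float(sum(weights[i, aa_index[aa]] for i, aa in enumerate(residues))))

    return Landscape(
        spec=spec,
        fn=fn,
        optimum_score=float(weights.max(axis=1).sum()),
        weights=weights,
    )


def plant_mutations(
    target: ProteinSequence, k: int, seed: int | np.random.Generator, id: str = "wt"
) -> ProteinSequence:
    """A sequence at Hamming distance exactly ``k`` from ``target``.

    Used to construct recovery problems: the returned sequence plays the
    wild type, and an optimizer with a mutation budget >= k can reach the
    target by recovering the k planted substitutions.
    """
    if not 0 <= k <= len(target):
        raise ValueError(f"k must be in 0..{len(target)}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    residues = list(target.residues)
    for pos in rng.choice(len(residues), size=k, replace=False):
        alternatives = [aa for aa in AMINO_ACIDS if aa != residues[pos]]
        residues[pos] = alternatives[int(rng.integers(len(alternatives)))]
    return ProteinSequence(id=id, residues="".join(residues))


def make_recovery_problem(
    length: int, planted: int, seed: int
) -> tuple[ProteinSequence, Landscape]:
    """A target-match landscape plus a WT ``planted`` mutations from its optimum."""
    landscape = make_landscape(LandscapeSpec(kind="target_match", length=length, seed=seed))
    assert landscape.target is not None
    wt = plant_mutations(landscape.target, planted, seed + 1)
    return wt, landscape


# --- labelled reaction datasets --------------------------------------------

def gaussian_bayes_auc(delta: float) -> float:
    """Bayes AUC of two unit-variance Gaussian classes a distance delta apart."""
    from scipy.stats import norm

    return float(norm.cdf(delta / np.sqrt(2.0)))


@dataclass(frozen=True)
class SyntheticReactionSpec:
    """Generator settings for a labelled substrate/product/enzyme corpus.

    ``separation`` is the Euclidean distance between the class-mean latent
    vectors (Bayes AUC = Phi(separation/sqrt 2)).  ``kcat_function`` names a
    monotone map from two enzyme-latent coordinates to log10 kcat;
    ``kcat_noise_sd`` is log-normal noise (sd on the log10 scale), matching
    the heavy right tail of measured turnover numbers.
    """

    n_reported: int = 250
    n_random: int = 250
    embed_dim: int = 8
    separation: float = 3.0
    kcat_function: Literal["linear2", "quadratic2"] = "linear2"
    kcat_noise_sd: float = 0.0
    enzyme_length: int = 40
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reported < 1 or self.n_random < 0:
            raise ValueError("need n_reported >= 1 and n_random >= 0")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2 (kcat uses two coordinates)")
        if self.separation < 0 or self.kcat_noise_sd < 0:
            raise ValueError("separation and kcat_noise_sd must be >= 0")


_KCAT_FUNCTIONS: dict[str, Callable[[np.ndarray], float]] = {
    # monotone in two enzyme-latent coordinates, on the log10 scale
    "linear2": lambda z: 1.2 * z[0] + 0.8 * z[1],
    "quadratic2": lambda z: 0.5 * (z[0] + z[1]) + 0.15 * (z[0] + z[1]) ** 2,
}


@dataclass
class SyntheticReactionDataset:
    """Generated records, their latents, and the embedder that reproduces them."""

    spec: SyntheticReactionSpec
    records: list[ReactionRecord]
    latents: dict[str, np.ndarray] = field(repr=False)
    substrate_embedder: TableEmbedder = field(repr=False)
    product_embedder: TableEmbedder = field(repr=False)
    enzyme_embedder: TableEmbedder = field(repr=False)

    @property
    def bayes_auc(self) -> float:
        return gaussian_bayes_auc(self.spec.separation)


def make_reaction_dataset(spec: SyntheticReactionSpec) -> SyntheticReactionDataset:
    """Draw a labelled reaction corpus with Gaussian latent class structure.

    Reported rows have latent mean +delta/2 along a unit direction of the
    concatenated (substrate, product, enzyme) latent space; random rows sit
    at -delta/2.  Strings are unique per record so the lookup embedders are
    well defined.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.embed_dim
    total_dim = 3 * d
    # class-mean shift concentrated on the first two coordinates of each
    # component's latent block: the Bayes ceiling Phi(sep/sqrt 2) depends only
    # on ||shift||, but axis-concentrated shifts keep the signal learnable by
    # axis-aligned tree splits, which is the point of the generator
    direction = np.zeros(total_dim)
    for block in range(3):
        direction[block * d] = 1.0
        direction[block * d + 1] = 1.0
    direction /= np.linalg.norm(direction)

    records: list[ReactionRecord] = []
    latents: dict[str, np.ndarray] = {}
    sub_table: dict[str, np.ndarray] = {}
    prod_table: dict[str, np.ndarray] = {}
    enz_table: dict[str, np.ndarray] = {}

    kcat_fn = _KCAT_FUNCTIONS[spec.kcat_function]

    def draw(label: str, index: int) -> ReactionRecord:
        shift = (spec.separation / 2.0) * direction
        mean = shift if label == "reported" else -shift
        z = rng.normal(0.0, 1.0, size=total_dim) + mean
        z_sub, z_prod, z_enz = z[:d], z[d : 2 * d], z[2 * d :]
        # syntactically plausible placeholder molecule strings (no real
        # chemistry); the dotted suffix keeps every record's strings unique
        substrate_id = f"{'C' * (2 + index % 6)}O.{label}{index}"
        product_id = f"{'C' * (2 + (index + 1) % 6)}N.{label}{index}"
        enzyme = random_protein(spec.enzyme_length, rng, id=f"enz-{label}-{index}")
        log10_kcat = kcat_fn(z_enz)
        if spec.kcat_noise_sd > 0:
            log10_kcat += float(rng.normal(0.0, spec.kcat_noise_sd))
        rec = ReactionRecord(
            substrate=substrate_id,
            product=product_id,
            enzyme=enzyme,
            label=label,  # type: ignore[arg-type]
            kcat=float(10.0**log10_kcat),
        )
        key = f"{label}-{index}"
        latents[key] = z
        sub_table[substrate_id] = z_sub
        prod_table[product_id] = z_prod
        enz_table[enzyme.residues] = z_enz
        return rec

    for i in range(spec.n_reported):
        records.append(draw("reported", i))
    for i in range(spec.n_random):
        records.append(draw("random", i))

    return SyntheticReactionDataset(
        spec=spec,
        records=records,
        latents=latents,
        substrate_embedder=TableEmbedder(dim=d, table=sub_table, fallback_salt=11),
        product_embedder=TableEmbedder(dim=d, table=prod_table, fallback_salt=22),
        enzyme_embedder=TableEmbedder(dim=d, table=enz_table, fallback_salt=33),
    )


# --- dihedral trajectory pairs ---------------------------------------------

@dataclass(frozen=True)
class Perturbation:
    """A localized, time-windowed angular shift applied to the mutant.

    ``residues`` are 1-based ids; ``time_window`` is an inclusive snapshot
    index range (0-based); ``amplitude_deg`` is added to the mutant's angles
    inside the residue x time window, emulating a conformational change.
    """

    residues: tuple[int, ...]
    time_window: tuple[int, int]
    amplitude_deg: float


@dataclass(frozen=True)
class SyntheticTrajectorySpec:
    """WT/mutant dihedral series sharing a smooth base motion.

    Each residue follows a sinusoidal base profile (its equilibrium angle
    plus a slow oscillation) and both trajectories add independent thermal
    noise, so unperturbed pairs differ only by noise and correlate strongly.
    Defaults give 200 snapshots at 100 ps spacing = a 20 ns window.  Base
    angles stay away from the +/-180 seam so wrapping does not dominate.
    """

    n_residues: int = 10
    n_snapshots: int = 200
    snapshot_spacing_ps: float = 100.0
    angle_kind: Literal["phi", "psi"] = "phi"
    base_amplitude_deg: float = 20.0
    thermal_noise_sd: float = 8.0
    perturbation: Perturbation | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_residues < 1 or self.n_snapshots < 2:
            raise ValueError("need n_residues >= 1 and n_snapshots >= 2")
        if self.thermal_noise_sd < 0:
            raise ValueError("thermal_noise_sd must be >= 0")
        if self.perturbation is not None:
            lo, hi = self.perturbation.time_window
            if not (0 <= lo <= hi < self.n_snapshots):
                raise ValueError("perturbation time window outside snapshot grid")
            for r in self.perturbation.residues:
                if not 1 <= r <= self.n_residues:
                    raise ValueError(f"perturbed residue {r} outside 1..{self.n_residues}")


def _wrap(angles: np.ndarray) -> np.ndarray:
    return (angles + 180.0) % 360.0 - 180.0


def make_trajectory_pair(
    spec: SyntheticTrajectorySpec,
) -> tuple[DihedralTrajectory, DihedralTrajectory]:
    """Generate a (wild-type, mutant) dihedral trajectory pair."""
    rng = np.random.default_rng(spec.seed)
    times = np.arange(spec.n_snapshots) * spec.snapshot_spacing_ps
    residue_ids = list(range(1, spec.n_residues + 1))

    centers = rng.uniform(-140.0, 140.0, size=spec.n_residues)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_residues)
    periods = rng.uniform(0.2, 0.6, size=spec.n_residues) * spec.n_snapshots

    t_idx = np.arange(spec.n_snapshots)
    base = centers[:, None] + spec.base_amplitude_deg * np.sin(
        2.0 * np.pi * t_idx[None, :] / periods[:, None] + phases[:, None]
    )

    wt = base + rng.normal(0.0, spec.thermal_noise_sd, size=base.shape)
    mut = base + rng.normal(0.0, spec.thermal_noise_sd, size=base.shape)

    if spec.perturbation is not None:
        p = spec.perturbation
        lo, hi = p.time_window
        rows = [r - 1 for r in p.residues]
        mut[np.ix_(rows, range(lo, hi + 1))] += p.amplitude_deg

    def build(name: str, angles: np.ndarray) -> DihedralTrajectory:
        return DihedralTrajectory(
            angle_kind=spec.angle_kind,
            snapshot_times=times.astype(float),
            angles=_wrap(angles),
            residue_ids=residue_ids,
            name=name,
        )

    return build("wt", wt), build("mut", mut)
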