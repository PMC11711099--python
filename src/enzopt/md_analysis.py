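"""Post-MD dihedral-angle analytics for mutant validation.

The toolkit never runs molecular dynamics; it consumes per-residue phi/psi
time series exported from any MD suite as plain tables (100 ps snapshot
spacing in the published protocol, last 20 ns analysed).  From those it
computes:

* ``f_sim(t')`` — a cumulative squared dihedral-deviation statistic between
  a mutant and its wild type,

      f_sim(t') = sum_{t=t'}^{t_max} sum_{i=1}^{i_max}
                  (theta_i_wt(t') - theta_i_mut(t))^2
                  / ((t_max - t') * i_max),

  with wrap-aware angle differences.  The default compares the wild type
  frozen at t' against the mutant at running t, exactly as the formula is
  written; a ``time-matched`` variant using theta_wt(t) is available since
  the prose reading admits both.  Note the denominator uses (t_max - t')
  although the sum has (t_max - t' + 1) terms; t' = t_max is excluded to
  keep it positive.
* per-residue Pearson correlations between WT and mutant angle series, with
  median/IQR summaries per angle kind;
* the two control-mutant generators used to contextualise best mutants:
  random re-mutations of the same positions, and a five-consecutive-proline
  substitution inside an alpha-helix (prolines kink helices, giving a
  deliberately disruptive control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .core_sequences import (
    AMINO_ACIDS,
    Mutation,
    MutantRecord,
    ProteinSequence,
    apply_mutations,
)


@dataclass(frozen=True)
class DihedralTrajectory:
    """Per-residue dihedral angles over uniformly spaced snapshots.

    ``angles`` is a residues x snapshots matrix in degrees, wrapped to
    [-180, 180).  ``snapshot_times`` are in ps and must be uniformly spaced;
    ``residue_ids`` are 1-based.
    """

    angle_kind: Literal["phi", "psi"]
    snapshot_times: np.ndarray
    angles: np.ndarray
    residue_ids: Sequence[int]
    name: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.snapshot_times, dtype=float)
        angles = np.asarray(self.angles, dtype=float)
        if self.angle_kind not in ("phi", "psi"):
            raise ValueError(f"angle_kind must be 'phi' or 'psi', got {self.angle_kind!r}")
        if times.ndim != 1 or times.size < 2:
            raise ValueError("need at least 2 snapshots")
        spacings = np.diff(times)
        if not np.allclose(spacings, spacings[0], atol=1e-6):
            raise ValueError("snapshot times must be uniformly spaced (within 1e-6 ps)")
        if angles.shape != (len(self.residue_ids), times.size):
            raise ValueError(
                f"angles shape {angles.shape} does not match "
                f"{len(self.residue_ids)} residues x {times.size} snapshots"
            )
        if (angles < -180.0).any() or (angles >= 180.0).any():
            raise ValueError("angles must lie in [-180, 180) degrees")
        object.__setattr__(self, "snapshot_times", times)
        object.__setattr__(self, "angles", angles)
        object.__setattr__(self, "residue_ids", list(self.residue_ids))

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def n_snapshots(self) -> int:
        return self.snapshot_times.size

    @property
    def spacing_ps(self) -> float:
        return float(self.snapshot_times[1] - self.snapshot_times[0])


@dataclass(frozen=True)
class HelixAnnotation:
    """Alpha-helical residue ranges, 1-based inclusive, non-overlapping."""

    ranges: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        rs = tuple(sorted((int(a), int(b)) for a, b in self.ranges))
        for a, b in rs:
            if a < 1 or b < a:
                raise ValueError(f"invalid helix range ({a}, {b})")
        for (a1, b1), (a2, b2) in zip(rs, rs[1:]):
            if a2 <= b1:
                raise ValueError(f"overlapping helix ranges ({a1},{b1}) and ({a2},{b2})")
        object.__setattr__(self, "ranges", rs)

    def eligible(self, min_length: int = 5) -> list[tuple[int, int]]:
        return [(a, b) for a, b in self.ranges if b - a + 1 >= min_length]


def angular_difference(a: float | np.ndarray, b: float | np.ndarray) -> float | np.ndarray:
    """Signed minimal circular difference a - b in (-180, 180] degrees."""
    d = (np.asarray(a, dtype=float) - np.asarray(b, dtype=float) + 180.0) % 360.0 - 180.0
    d = np.where(d == -180.0, 180.0, d)
    if np.ndim(d) == 0:
        return float(d)
    return d


def _check_grids(wt: DihedralTrajectory, mut: DihedralTrajectory) -> None:
    if wt.residue_ids != mut.residue_ids:
        raise ValueError("wild-type and mutant trajectories cover different residues")
    if wt.snapshot_times.shape != mut.snapshot_times.shape or not np.allclose(
        wt.snapshot_times, mut.snapshot_times, atol=1e-6
    ):
        raise ValueError("wild-type and mutant snapshot grids differ; no interpolation is attempted")


def f_sim(
    wt: DihedralTrajectory,
    mut: DihedralTrajectory,
    t_prime: int,
    variant: Literal["printed", "time-matched"] = "printed",
) -> float:
    """Dihedral-deviation statistic at snapshot index ``t_prime`` (0-based).

    ``printed`` freezes the wild type at t' (the formula as written);
    ``time-matched`` compares both trajectories at the running time t.
    ``t_prime`` must be strictly before the last snapshot.
    """
    _check_grids(wt, mut)
    t_max = wt.n_snapshots - 1
    if not 0 <= t_prime < t_max:
        raise ValueError(f"t_prime must be in 0..{t_max - 1} (t'=t_max excluded)")
    mut_block = mut.angles[:, t_prime:]
    if variant == "printed":
        ref = wt.angles[:, t_prime][:, None]
    elif variant == "time-matched":
        ref = wt.angles[:, t_prime:]
    else:
        raise ValueError(f"unknown variant {variant!r}")
    sq = np.asarray(angular_difference(ref, mut_block)) ** 2
    return float(sq.sum() / ((t_max - t_prime) * wt.n_residues))


def f_sim_profile(
    wt: DihedralTrajectory,
    mut: DihedralTrajectory,
    window_ns: float | None = 20.0,
    variant: Literal["printed", "time-matched"] = "printed",
) -> pd.DataFrame:
    """``f_sim`` at every admissible t' in the analysis window.

    ``window_ns`` selects the trailing window of the trajectory (default the
    last 20 ns); ``None`` uses all snapshots.  The last snapshot is never an
    admissible t'.  Returns a DataFrame with columns ``t_prime`` (index),
    ``time_ps`` and ``f_sim``.
    """
    _check_grids(wt, mut)
    times = wt.snapshot_times
    if window_ns is None:
        start_idx = 0
    else:
        cutoff = times[-1] - window_ns * 1000.0
        start_idx = int(np.searchsorted(times, cutoff, side="left"))
    t_primes = list(range(start_idx, wt.n_snapshots - 1))
    if not t_primes:
        raise ValueError("analysis window contains no admissible t'")
    return pd.DataFrame(
        {
            "t_prime": t_primes,
            "time_ps": times[t_primes],
            "f_sim": [f_sim(wt, mut, tp, variant) for tp in t_primes],
        }
    )


@dataclass
class CorrelationSummary:
    """Per-residue WT-vs-mutant Pearson correlations and their distribution."""

    angle_kind: str
    per_residue: dict[int, float]
    median: float
    iqr: float
    skipped_residues: list[int]


def dihedral_correlations(
    wt: DihedralTrajectory, mut: DihedralTrajectory
) -> CorrelationSummary:
    """Pearson r between WT and mutant angle series, one per residue.

    Residues whose series have zero variance in either trajectory are
    skipped with a warning (correlation undefined).
    """
    _check_grids(wt, mut)
    if wt.n_snapshots < 3:
        raise ValueError("correlation needs at least 3 snapshots")
    per_residue: dict[int, float] = {}
    skipped: list[int] = []
    for row, rid in enumerate(wt.residue_ids):
        x = wt.angles[row]
        y = mut.angles[row]
        if np.var(x) == 0 or np.var(y) == 0:
            skipped.append(rid)
            continue
        per_residue[rid] = float(np.corrcoef(x, y)[0, 1])
    if skipped:
        warnings.warn(
            f"skipped zero-variance residues {skipped} in correlation analysis",
            stacklevel=2,
        )
    values = np.array(list(per_residue.values()))
    if values.size == 0:
        raise ValueError("no residue had nonzero variance in both trajectories")
    q1, q3 = np.percentile(values, [25, 75])
    return CorrelationSummary(
        angle_kind=wt.angle_kind,
        per_residue=per_residue,
        median=float(np.median(values)),
        iqr=float(q3 - q1),
        skipped_residues=skipped,
    )


# --- control-mutant generators ----------------------------------------------

def make_random_controls(
    wild_type: ProteinSequence,
    best: MutantRecord,
    n: int = 5,
    rng: np.random.Generator | int = 0,
    exclude_wild_type: bool = True,
) -> list[MutantRecord]:
    """Random controls re-mutating exactly the best mutant's positions.

    At each position the replacement is drawn uniformly over the alphabet
    excluding the best mutant's residue there; with ``exclude_wild_type``
    (default) the WT residue is excluded too, so every control is a genuine
    mutation at every position.  Five controls per reaction is the
    convention this mirrors.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not best.mutations:
        raise ValueError("best mutant has no mutations to randomize")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    controls = []
    for k in range(n):
        mutations = []
        for m in best.mutations:
            forbidden = {m.new_residue}
            if exclude_wild_type:
                forbidden.add(m.wt_residue)
            else:
                forbidden.add(m.wt_residue)  # a Mutation cannot be a no-op anyway
            pool = [aa for aa in AMINO_ACIDS if aa not in forbidden]
            new_aa = pool[int(rng.integers(len(pool)))]
            mutations.append(
                Mutation(position=m.position, wt_residue=m.wt_residue, new_residue=new_aa)
            )
        seq = apply_mutations(wild_type, mutations, child_id=f"{wild_type.id}|random-control-{k}")
        controls.append(
            MutantRecord(parent_id=wild_type.id, mutations=tuple(mutations), sequence=seq)
        )
    return controls


def make_proline_control(
    wild_type: ProteinSequence,
    helices: HelixAnnotation,
    rng: np.random.Generator | int = 0,
) -> MutantRecord:
    """Substitute five consecutive prolines inside a randomly chosen helix.

    The five-residue window is placed uniformly inside a uniformly chosen
    helix of length >= 5.  Substitution (not insertion) keeps the sequence
    length fixed, which every pairwise analysis in this module requires.
    Positions already holding proline are left as-is (they are already
    proline, not a mutation).
    """
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    eligible = [
        (a, b) for a, b in helices.eligible(5) if b <= len(wild_type)
    ]
    if not eligible:
        raise ValueError("no helix of length >= 5 within the sequence")
    a, b = eligible[int(rng.integers(len(eligible)))]
    start = a + int(rng.integers(b - a - 5 + 2))  # window [start, start+4] within [a, b]
    mutations = []
    for pos in range(start, start + 5):
        wt_aa = wild_type[pos]
        if wt_aa == "P":
            continue
        mutations.append(Mutation(position=pos, wt_residue=wt_aa, new_residue="P"))
    seq = apply_mutations(
        wild_type, mutations, child_id=f"{wild_type.id}|proline-control-{start}"
    )
    return MutantRecord(parent_id=wild_type.id, mutations=tuple(mutations), sequence=seq)


# --- tabular I/O -------------------------------------------------------------

DIHEDRAL_COLUMNS = ["time_ps", "residue", "phi_deg", "psi_deg"]


def read_dihedral_table(path: str | Path, name: str = "") -> dict[str, DihedralTrajectory]:
    """Read a TSV/CSV dihedral table into {'phi': ..., 'psi': ...}.

    Expected columns: time_ps, residue, phi_deg, psi_deg — the long format
    standard trajectory analysis tools export.  Separator is inferred from
    the extension (.tsv/.txt → tab, otherwise comma).
    """
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    df = pd.read_csv(path, sep=sep)
    missing = set(DIHEDRAL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"dihedral table {path} missing columns {sorted(missing)}")
    times = np.sort(df["time_ps"].unique()).astype(float)
    residues = sorted(int(r) for r in df["residue"].unique())
    out = {}
    for kind, col in (("phi", "phi_deg"), ("psi", "psi_deg")):
        pivot = df.pivot_table(index="residue", columns="time_ps", values=col)
        pivot = pivot.loc[residues, times]
        if pivot.isna().any().any():
            raise ValueError(f"dihedral table {path}: missing {kind} angles on the grid")
        out[kind] = DihedralTrajectory(
            angle_kind=kind,  # type: ignore[arg-type]
            snapshot_times=times,
            angles=pivot.to_numpy(dtype=float),
            residue_ids=residues,
            name=name or Path(str(path)).stem,
        )
    return out


def write_dihedral_table(
    phi: DihedralTrajectory, psi: DihedralTrajectory, path: str | Path
) -> None:
    """Write matched phi/psi trajectories as a long-format table."""
    if phi.residue_ids != psi.residue_ids or not np.allclose(
        phi.snapshot_times, psi.snapshot_times
    ):
        raise ValueError("phi and psi trajectories must share the same grid")
    rows = []
    for row, rid in enumerate(phi.residue_ids):
        for col, t in enumerate(phi.snapshot_times):
            rows.append(
                {
                    "time_ps": float(t),
                    "residue": rid,
                    "phi_deg": float(phi.angles[row, col]),
                    "psi_deg": float(psi.angles[row, col]),
                }
            )
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    pd.DataFrame(rows, columns=DIHEDRAL_COLUMNS).to_csv(path, sep=sep, index=False)


# --- foldability stub ---------------------------------------------------------

class FoldabilityPredictor:  # pragma: no cover - interface stub
    """Interface stub for per-residue fold-confidence (pLDDT-style) scoring.

    Structure-prediction models are outside this package; an adapter
    implementing ``predict_plddt(sequence) -> list[float]`` can be plugged
    into downstream reporting without changing any analysis here.
    """

    def predict_plddt(self, sequence: ProteinSequence) -> list[float]:
        raise NotImplementedError


def predict_plddt_stub(sequence: ProteinSequence) -> None:
    """Placeholder: foldability scoring requires an external structure model."""
    raise NotImplementedError(
        "foldability (pLDDT) scoring requires an external structure-prediction "
        "model; plug in an adapter implementing predict_plddt(sequence)"
    )
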