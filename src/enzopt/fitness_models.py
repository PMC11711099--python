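"""Trainable fitness functions and the statistics around them.

Two models score enzyme mutants against a reaction context:

* **Feasibility** — a random forest (100 trees, Gini splitting, five-fold
  cross-validation) classifying substrate/product/enzyme triples as
  "reported" (a verified biocatalytic association) versus "random" (a
  shuffled association).  Its positive-class vote fraction is the
  feasibility score F_s in [0, 1], with 0.5 the reported/random boundary.
* **Turnover** — an XGBoost regressor for the turnover number kcat (s^-1),
  fitted on log10(kcat) with learning_rate 0.09, max_delta_step 1.19,
  min_child_weight 2.82, reg_alpha 1.94, reg_lambda 4.95.

Both consume concatenated numeric embeddings of substrate, product and
enzyme.  Embedders are a plugin contract: deterministic map from a string
to a fixed-length vector.  The package ships a hash-projection embedder (no
signal, for plumbing) and a lookup-table embedder the synthetic generator
fills with its latent coordinates (for model-recovery tests); adapters to
pretrained chemistry/protein models can implement the same contract.

The module also houses the mutant-vs-WT delta statistic
(delta = X_mutant - X_WT per reaction), the median-kcat split, and a
Mann-Whitney U test with an exact small-sample branch.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Iterable, Literal, Protocol, Sequence, runtime_checkable

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import mean_squared_error, r2_score, roc_auc_score
from sklearn.model_selection import StratifiedKFold, train_test_split
from xgboost import XGBRegressor

from .core_sequences import ProteinSequence

MODEL_FORMAT_VERSION = 1

#: Hyperparameters of the turnover-number regressor.
KCAT_HYPERPARAMS: dict[str, float] = {
    "learning_rate": 0.09,
    "max_delta_step": 1.19,
    "min_child_weight": 2.82,
    "reg_alpha": 1.94,
    "reg_lambda": 4.95,
}


@dataclass(frozen=True)
class ReactionRecord:
    """One substrate → product transformation with its enzyme.

    ``label`` marks verified ("reported") versus shuffled ("random")
    associations; ``kcat`` is the turnover number in s^-1 when known.
    """

    substrate: str
    product: str
    enzyme: ProteinSequence
    label: Literal["reported", "random"] | None = None
    kcat: float | None = None
    ec_class: str | None = None

    def __post_init__(self) -> None:
        if self.label is not None and self.label not in ("reported", "random"):
            raise ValueError(f"label must be 'reported' or 'random', got {self.label!r}")
        if self.kcat is not None and not self.kcat > 0:
            raise ValueError(f"kcat must be positive, got {self.kcat}")

    @property
    def triple(self) -> tuple[str, str, str]:
        return (self.substrate, self.product, self.enzyme.residues)


@runtime_checkable
class Embedder(Protocol):
    """Deterministic map from a string to a fixed-length numeric vector."""

    dim: int

    def __call__(self, text: str) -> np.ndarray: ...


@dataclass(frozen=True)
class HashEmbedder:
    """Signal-free deterministic embedder: a hash-seeded Gaussian projection.

    Stable across processes (sha256, not Python's salted ``hash``); useful
    wherever only the plumbing matters, and as the fallback for strings a
    lookup table has never seen.
    """

    dim: int
    salt: int = 0

    def __call__(self, text: str) -> np.ndarray:
        digest = hashlib.sha256(f"{self.salt}:{text}".encode()).digest()
        seed = int.from_bytes(digest[:4], "little")
        return np.random.default_rng(seed).normal(0.0, 1.0, size=self.dim)


@dataclass
class TableEmbedder:
    """Lookup-table embedder filled by the synthetic generator.

    Known strings return their stored latent vector; unknown strings fall
    back to a hash projection so GA-proposed mutants remain scoreable.
    """

    dim: int
    table: dict[str, np.ndarray] = field(default_factory=dict, repr=False)
    fallback_salt: int = 0

    def __call__(self, text: str) -> np.ndarray:
        vec = self.table.get(text)
        if vec is not None:
            return np.asarray(vec, dtype=float)
        return HashEmbedder(dim=self.dim, salt=self.fallback_salt)(text)


def featurize(
    record: ReactionRecord,
    substrate_embedder: Embedder,
    product_embedder: Embedder,
    enzyme_embedder: Embedder,
) -> np.ndarray:
    """Concatenate [substrate ‖ product ‖ enzyme] embeddings."""
    parts = []
    for emb, text in (
        (substrate_embedder, record.substrate),
        (product_embedder, record.product),
        (enzyme_embedder, record.enzyme.residues),
    ):
        vec = np.asarray(emb(text), dtype=float)
        if vec.shape != (emb.dim,):
            raise ValueError(
                f"embedder declared dim {emb.dim} but returned shape {vec.shape}"
            )
        parts.append(vec)
    return np.concatenate(parts)


def _feature_matrix(
    rows: Sequence[ReactionRecord], embedders: tuple[Embedder, Embedder, Embedder]
) -> np.ndarray:
    return np.vstack([featurize(r, *embedders) for r in rows])


# --- negative-pair augmentation --------------------------------------------

def make_negative_pairs(
    reported: Sequence[ReactionRecord],
    rng: np.random.Generator | int = 0,
    max_retries: int = 100,
) -> list[ReactionRecord]:
    """Build "random" associations by shuffling the three columns independently.

    The substrate, product and enzyme columns of the reported records are
    permuted independently until no generated triple coincides with any
    reported triple; colliding rows are re-permuted up to ``max_retries``
    rounds.  Output count equals input count, all labelled "random".
    """
    if len(reported) < 3:
        raise ValueError("need at least 3 reported records to derange triples")
    if isinstance(rng, int):
        rng = np.random.default_rng(rng)
    reported_triples = {r.triple for r in reported}
    n = len(reported)
    subs = [r.substrate for r in reported]
    prods = [r.product for r in reported]
    enzs = [r.enzyme for r in reported]

    for _ in range(max_retries):
        si = rng.permutation(n)
        pi = rng.permutation(n)
        ei = rng.permutation(n)
        triples = [
            (subs[si[i]], prods[pi[i]], enzs[ei[i]].residues) for i in range(n)
        ]
        if not any(t in reported_triples for t in triples):
            return [
                ReactionRecord(
                    substrate=subs[si[i]],
                    product=prods[pi[i]],
                    enzyme=enzs[ei[i]],
                    label="random",
                )
                for i in range(n)
            ]
    raise ValueError(
        f"could not avoid reported triples after {max_retries} shuffles; "
        "input is too small or too degenerate"
    )


# --- feasibility model ------------------------------------------------------

@dataclass
class FeasibilityModel:
    """Fitted reported-vs-random classifier with its cross-validation summary."""

    estimator: RandomForestClassifier
    feature_dim: int
    cv_aucs: list[float]
    seed: int

    @property
    def mean_cv_auc(self) -> float:
        return float(np.mean(self.cv_aucs))


def train_feasibility(
    rows: Sequence[ReactionRecord],
    substrate_embedder: Embedder,
    product_embedder: Embedder,
    enzyme_embedder: Embedder,
    folds: int = 5,
    seed: int = 0,
    n_trees: int = 100,
) -> FeasibilityModel:
    """Train the random-forest feasibility classifier with k-fold CV.

    Per-fold AUC is computed on the held-out fold; the returned estimator is
    refit on all rows.
    """
    labelled = [r for r in rows if r.label is not None]
    y = np.array([1 if r.label == "reported" else 0 for r in labelled])
    if len(set(y.tolist())) < 2:
        raise ValueError("feasibility training needs both 'reported' and 'random' rows")
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"need at least {folds} rows per label for {folds}-fold CV, got {counts.tolist()}"
        )
    embedders = (substrate_embedder, product_embedder, enzyme_embedder)
    X = _feature_matrix(labelled, embedders)

    def fresh() -> RandomForestClassifier:
        return RandomForestClassifier(
            n_estimators=n_trees, criterion="gini", random_state=seed
        )

    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    aucs = []
    for train_idx, test_idx in cv.split(X, y):
        est = fresh().fit(X[train_idx], y[train_idx])
        proba = est.predict_proba(X[test_idx])[:, list(est.classes_).index(1)]
        aucs.append(float(roc_auc_score(y[test_idx], proba)))

    final = fresh().fit(X, y)
    return FeasibilityModel(
        estimator=final, feature_dim=X.shape[1], cv_aucs=aucs, seed=seed
    )


def predict_feasibility(
    model: FeasibilityModel,
    record: ReactionRecord,
    substrate_embedder: Embedder,
    product_embedder: Embedder,
    enzyme_embedder: Embedder,
) -> float:
    """Feasibility score F_s: the forest's vote fraction for "reported"."""
    x = featurize(record, substrate_embedder, product_embedder, enzyme_embedder)
    if x.shape[0] != model.feature_dim:
        raise ValueError(
            f"feature dimension {x.shape[0]} does not match model ({model.feature_dim})"
        )
    proba = model.estimator.predict_proba(x.reshape(1, -1))[0]
    return float(proba[list(model.estimator.classes_).index(1)])


# --- turnover-number model ---------------------------------------------------

@dataclass
class KcatModel:
    """Fitted log-scale turnover regressor with held-out metrics.

    Predictions are on the log scale (base ``log_base``); ``mse``, ``r2``
    and ``pearson_r`` are measured on a held-out split before the final
    refit on all rows.
    """

    estimator: XGBRegressor
    feature_dim: int
    log_base: float
    mse: float
    r2: float
    pearson_r: float
    seed: int


def _log(x: np.ndarray, base: float) -> np.ndarray:
    return np.log(x) / np.log(base)


def train_kcat(
    rows: Sequence[ReactionRecord],
    substrate_embedder: Embedder,
    enzyme_embedder: Embedder,
    hyperparams: dict[str, float] | None = None,
    seed: int = 0,
    log_base: float = 10.0,
    n_estimators: int = 200,
    log_transform: bool = True,
    test_fraction: float = 0.2,
) -> KcatModel:
    """Train the XGBoost turnover-number regressor on log-transformed kcat.

    Uses substrate and enzyme embeddings only (the product adds no
    information about turnover of a fixed transformation).  Metrics come
    from a random 80/20 held-out split; the returned estimator is refit on
    all rows.  ``log_transform=False`` fits raw kcat (kept for ablation);
    metrics are then still reported on the log scale so fits are comparable.
    """
    usable = [r for r in rows if r.kcat is not None]
    if not usable:
        raise ValueError("no rows with kcat")
    for r in usable:
        if not r.kcat > 0:
            raise ValueError(f"kcat must be positive, got {r.kcat}")
    X = np.vstack(
        [
            np.concatenate(
                [
                    np.asarray(substrate_embedder(r.substrate), dtype=float),
                    np.asarray(enzyme_embedder(r.enzyme.residues), dtype=float),
                ]
            )
            for r in usable
        ]
    )
    kcat = np.array([r.kcat for r in usable], dtype=float)
    y = _log(kcat, log_base) if log_transform else kcat

    params = dict(KCAT_HYPERPARAMS)
    params.update(hyperparams or {})

    def fresh() -> XGBRegressor:
        return XGBRegressor(
            n_estimators=n_estimators, random_state=seed, verbosity=0, **params
        )

    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_fraction, random_state=seed
    )
    est = fresh().fit(X_tr, y_tr)
    pred = est.predict(X_te)
    if not log_transform:  # report on the log scale regardless of target scale
        eps = np.finfo(float).tiny
        pred_log = _log(np.clip(pred, eps, None), log_base)
        true_log = _log(np.clip(y_te, eps, None), log_base)
    else:
        pred_log, true_log = pred, y_te

    mse = float(mean_squared_error(true_log, pred_log))
    if np.var(true_log) == 0 or np.var(pred_log) == 0:
        r2, pearson = 0.0, 0.0  # degenerate split: constant target or prediction
    else:
        r2 = float(r2_score(true_log, pred_log))
        pearson = float(np.corrcoef(true_log, pred_log)[0, 1])

    final = fresh().fit(X, y)
    return KcatModel(
        estimator=final,
        feature_dim=X.shape[1],
        log_base=log_base,
        mse=mse,
        r2=r2,
        pearson_r=pearson,
        seed=seed,
    )


def predict_kcat_log(
    model: KcatModel,
    record: ReactionRecord,
    substrate_embedder: Embedder,
    enzyme_embedder: Embedder,
) -> float:
    """Predicted log-scale kcat for one record."""
    x = np.concatenate(
        [
            np.asarray(substrate_embedder(record.substrate), dtype=float),
            np.asarray(enzyme_embedder(record.enzyme.residues), dtype=float),
        ]
    )
    if x.shape[0] != model.feature_dim:
        raise ValueError(
            f"feature dimension {x.shape[0]} does not match model ({model.feature_dim})"
        )
    return float(model.estimator.predict(x.reshape(1, -1))[0])


# --- delta statistics and tests ---------------------------------------------

@dataclass(frozen=True)
class DeltaStat:
    """Per-reaction change of a fitness metric: delta = X_mutant - X_WT."""

    reaction_id: str
    x_wt: float
    x_mutant: float

    @property
    def delta(self) -> float:
        return self.x_mutant - self.x_wt


def delta_scores(
    wt_scores: dict[str, float], mutant_scores: dict[str, float]
) -> list[DeltaStat]:
    """Pair WT and mutant scores by reaction id and compute deltas."""
    unpaired = set(wt_scores) ^ set(mutant_scores)
    if unpaired:
        raise ValueError(f"unpaired reaction ids: {sorted(unpaired)}")
    return [
        DeltaStat(reaction_id=rid, x_wt=wt_scores[rid], x_mutant=mutant_scores[rid])
        for rid in sorted(wt_scores)
    ]


def split_by_median(values: dict[str, float]) -> tuple[dict[str, float], dict[str, float]]:
    """Split keyed values at their median m: low = {v < m}, high = {v >= m}."""
    if len(values) < 2:
        raise ValueError("median split needs at least 2 values")
    m = float(np.median(list(values.values())))
    low = {k: v for k, v in values.items() if v < m}
    high = {k: v for k, v in values.items() if v >= m}
    return low, high


_EXACT_LIMIT = 12  # exact enumeration is cheap up to C(12, k) subsets


def mann_whitney_u(
    group_a: Sequence[float],
    group_b: Sequence[float],
    alternative: Literal["two-sided", "less", "greater"] = "two-sided",
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of group A, p-value).

    U is computed from midrank rank sums.  The p-value is exact (full
    enumeration of group assignments) when nA + nB <= 12 and there are no
    ties, otherwise a normal approximation with tie correction and
    continuity correction is used.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    combined = np.concatenate([a, b])
    # midranks
    order = np.argsort(combined, kind="mergesort")
    ranks = np.empty_like(combined)
    sorted_vals = combined[order]
    i = 0
    rank_values = np.empty_like(sorted_vals)
    while i < len(sorted_vals):
        j = i
        while j + 1 < len(sorted_vals) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        rank_values[i : j + 1] = (i + j) / 2.0 + 1.0
        i = j + 1
    ranks[order] = rank_values
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)

    has_ties = len(np.unique(combined)) < combined.size
    if na + nb <= _EXACT_LIMIT and not has_ties:
        p = _exact_mwu_p(combined, na, u_a, alternative)
    else:
        p = _asymptotic_mwu_p(combined, na, nb, u_a, alternative)
    return u_a, p


def _count_greater_pairs(a: np.ndarray, b: np.ndarray) -> float:
    return float(sum(1.0 if x > y else (0.5 if x == y else 0.0) for x in a for y in b))


def _exact_mwu_p(
    combined: np.ndarray, na: int, u_obs: float, alternative: str
) -> float:
    """Exact p by enumerating all C(n, na) assignments of the pooled values."""
    n = combined.size
    idx = range(n)
    us = []
    for a_idx in combinations(idx, na):
        mask = np.zeros(n, dtype=bool)
        mask[list(a_idx)] = True
        us.append(_count_greater_pairs(combined[mask], combined[~mask]))
    us = np.asarray(us)
    total = us.size
    eps = 1e-12
    if alternative == "greater":
        return float((us >= u_obs - eps).sum() / total)
    if alternative == "less":
        return float((us <= u_obs + eps).sum() / total)
    mean = na * (n - na) / 2.0
    dev = abs(u_obs - mean)
    return float(min(1.0, ((np.abs(us - mean) >= dev - eps).sum()) / total))


def _asymptotic_mwu_p(
    combined: np.ndarray, na: int, nb: int, u_a: float, alternative: str
) -> float:
    """Normal approximation with tie and continuity corrections."""
    from scipy.stats import norm

    n = na + nb
    mean = na * nb / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)))
    var = na * nb / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 1.0
    sd = math.sqrt(var)
    if alternative == "two-sided":
        z = (abs(u_a - mean) - 0.5) / sd
        return float(min(1.0, 2.0 * norm.sf(z)))
    if alternative == "greater":
        z = (u_a - mean - 0.5) / sd
        return float(norm.sf(z))
    z = (u_a - mean + 0.5) / sd
    return float(norm.cdf(z))


# --- reaction-table and model I/O -------------------------------------------

REACTION_COLUMNS = ["substrate_smiles", "product_smiles", "enzyme_seq", "label", "kcat_s1", "ec_class"]


def read_reaction_table(path: str | Path) -> list[ReactionRecord]:
    """Read a reaction CSV (columns substrate_smiles, product_smiles,
    enzyme_seq, label, kcat_s1, ec_class; the last three optional)."""
    df = pd.read_csv(path)
    missing = {"substrate_smiles", "product_smiles", "enzyme_seq"} - set(df.columns)
    if missing:
        raise ValueError(f"reaction table {path} missing columns {sorted(missing)}")
    records = []
    for i, row in df.iterrows():
        label = row.get("label")
        kcat = row.get("kcat_s1")
        ec = row.get("ec_class")
        records.append(
            ReactionRecord(
                substrate=str(row["substrate_smiles"]),
                product=str(row["product_smiles"]),
                enzyme=ProteinSequence(id=f"row{i}", residues=str(row["enzyme_seq"])),
                label=None if pd.isna(label) else str(label),  # type: ignore[arg-type]
                kcat=None if pd.isna(kcat) else float(kcat),
                ec_class=None if ec is None or pd.isna(ec) else str(ec),
            )
        )
    return records


def write_reaction_table(records: Iterable[ReactionRecord], path: str | Path) -> None:
    rows = [
        {
            "substrate_smiles": r.substrate,
            "product_smiles": r.product,
            "enzyme_seq": r.enzyme.residues,
            "label": r.label,
            "kcat_s1": r.kcat,
            "ec_class": r.ec_class,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=REACTION_COLUMNS).to_csv(path, index=False)


def save_model(model: FeasibilityModel | KcatModel, path: str | Path, config: dict | None = None) -> None:
    """Serialize a fitted model with format version, config and seed embedded."""
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "kind": type(model).__name__,
            "model": model,
            "config": config or {},
            "seed": model.seed,
        },
        path,
    )


def load_model(path: str | Path) -> FeasibilityModel | KcatModel:
    payload = joblib.load(path)
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"unsupported model format version {payload.get('format_version')!r}"
        )
    return payload["model"]
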