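"""Feasibility/turnover models, negative sampling, delta stats, rank tests."""

import itertools

import numpy as np
import pytest
from scipy.stats import mannwhitneyu as scipy_mwu

from enzopt.core_sequences import ProteinSequence
from enzopt.fitness_models import (
    DeltaStat,
    HashEmbedder,
    ReactionRecord,
    delta_scores,
    featurize,
    load_model,
    make_negative_pairs,
    mann_whitney_u,
    predict_feasibility,
    predict_kcat_log,
    save_model,
    split_by_median,
    train_feasibility,
    train_kcat,
)
from enzopt.synthetic_data import SyntheticReactionSpec, make_reaction_dataset


def _records(n=6, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        out.append(
            ReactionRecord(
                substrate=f"CC{i}",
                product=f"CO{i}",
                enzyme=ProteinSequence(id=f"e{i}", residues="MKTAYIAKQR"[: 5 + i % 5] + "AAAAA"),
                label="reported",
                kcat=float(10 ** rng.normal()),
            )
        )
    return out


class TestReactionRecord:
    def test_rejects_nonpositive_kcat(self):
        with pytest.raises(ValueError):
            ReactionRecord(
                substrate="C", product="O",
                enzyme=ProteinSequence(id="e", residues="MKT"), kcat=0.0,
            )

    def test_rejects_unknown_label(self):
        with pytest.raises(ValueError):
            ReactionRecord(
                substrate="C", product="O",
                enzyme=ProteinSequence(id="e", residues="MKT"), label="maybe",
            )


class TestNegativePairs:
    def test_no_output_triple_is_reported(self):
        reported = _records(8)
        negatives = make_negative_pairs(reported, np.random.default_rng(0))
        assert len(negatives) == len(reported)
        reported_triples = {r.triple for r in reported}
        assert all(n.triple not in reported_triples for n in negatives)

    def test_all_labelled_random(self):
        assert all(n.label == "random" for n in make_negative_pairs(_records(5), 1))

    def test_reproducible_per_seed(self):
        a = make_negative_pairs(_records(6), np.random.default_rng(3))
        b = make_negative_pairs(_records(6), np.random.default_rng(3))
        assert [x.triple for x in a] == [x.triple for x in b]

    def test_too_few_records_rejected(self):
        with pytest.raises(ValueError):
            make_negative_pairs(_records(2), 0)


class TestFeaturize:
    def test_concatenated_dimensions(self):
        r = _records(1)[0]
        vec = featurize(r, HashEmbedder(4, 1), HashEmbedder(4, 2), HashEmbedder(8, 3))
        assert vec.shape == (16,)

    def test_deterministic(self):
        r = _records(1)[0]
        e = (HashEmbedder(4, 1), HashEmbedder(4, 2), HashEmbedder(8, 3))
        np.testing.assert_array_equal(featurize(r, *e), featurize(r, *e))

    def test_zero_embedders_give_zero_vector(self):
        class Zero:
            dim = 5
            def __call__(self, text):
                return np.zeros(5)

        vec = featurize(_records(1)[0], Zero(), Zero(), Zero())
        np.testing.assert_array_equal(vec, np.zeros(15))

    def test_dimension_mismatch_rejected(self):
        class Lying:
            dim = 5
            def __call__(self, text):
                return np.zeros(3)

        with pytest.raises(ValueError, match="declared dim"):
            featurize(_records(1)[0], Lying(), Lying(), Lying())


@pytest.fixture(scope="module")
def feasibility_model(separable_dataset=None):
    ds = make_reaction_dataset(
        SyntheticReactionSpec(n_reported=100, n_random=100, separation=3.0, seed=5)
    )
    model = train_feasibility(
        ds.records,
        ds.substrate_embedder,
        ds.product_embedder,
        ds.enzyme_embedder,
        seed=0,
    )
    return ds, model


class TestFeasibilityModel:
    def test_separable_dataset_high_cv_auc(self, feasibility_model):
        ds, model = feasibility_model
        assert model.mean_cv_auc >= 0.9
        assert len(model.cv_aucs) == 5

    def test_reported_row_scores_above_half(self, feasibility_model):
        ds, model = feasibility_model
        row = next(r for r in ds.records if r.label == "reported")
        fs = predict_feasibility(
            model, row, ds.substrate_embedder, ds.product_embedder, ds.enzyme_embedder
        )
        assert 0.5 < fs <= 1.0

    def test_flipped_labels_flip_the_score(self, feasibility_model):
        ds, _ = feasibility_model
        from dataclasses import replace

        flipped = [
            replace(r, label="random" if r.label == "reported" else "reported")
            for r in ds.records
        ]
        model = train_feasibility(
            flipped, ds.substrate_embedder, ds.product_embedder, ds.enzyme_embedder, seed=0
        )
        row = next(r for r in ds.records if r.label == "reported")
        fs = predict_feasibility(
            model, row, ds.substrate_embedder, ds.product_embedder, ds.enzyme_embedder
        )
        assert fs < 0.5

    def test_scores_bounded(self, feasibility_model):
        ds, model = feasibility_model
        for r in ds.records[::40]:
            fs = predict_feasibility(
                model, r, ds.substrate_embedder, ds.product_embedder, ds.enzyme_embedder
            )
            assert 0.0 <= fs <= 1.0

    def test_single_class_rejected(self):
        rows = _records(12)
        e = (HashEmbedder(4, 1), HashEmbedder(4, 2), HashEmbedder(8, 3))
        with pytest.raises(ValueError):
            train_feasibility(rows, *e)

    def test_model_round_trips_through_disk(self, feasibility_model, tmp_path):
        ds, model = feasibility_model
        path = tmp_path / "model.joblib"
        save_model(model, path)
        back = load_model(path)
        row = ds.records[0]
        args = (ds.substrate_embedder, ds.product_embedder, ds.enzyme_embedder)
        assert predict_feasibility(back, row, *args) == predict_feasibility(
            model, row, *args
        )


class TestKcatModel:
    def test_noiseless_monotone_function_recovered(self):
        ds = make_reaction_dataset(
            SyntheticReactionSpec(
                n_reported=400, n_random=0, separation=0.0, kcat_noise_sd=0.0, seed=9
            )
        )
        model = train_kcat(ds.records, ds.substrate_embedder, ds.enzyme_embedder, seed=0)
        assert model.r2 >= 0.8
        assert model.pearson_r >= 0.9

    def test_constant_kcat_handled(self):
        rows = [
            ReactionRecord(
                substrate=f"C{i}", product=f"O{i}",
                enzyme=ProteinSequence(id=f"e{i}", residues="MKTAYIAKQR"),
                kcat=2.0,
            )
            for i in range(30)
        ]
        e_sub, e_enz = HashEmbedder(4, 1), HashEmbedder(8, 3)
        model = train_kcat(rows, e_sub, e_enz, seed=0)
        assert model.r2 == 0.0
        assert model.mse == pytest.approx(0.0, abs=1e-6)

    def test_no_kcat_rows_rejected(self):
        rows = [
            ReactionRecord(
                substrate="C", product="O",
                enzyme=ProteinSequence(id="e", residues="MKT"), label="reported",
            )
        ]
        with pytest.raises(ValueError):
            train_kcat(rows, HashEmbedder(4, 1), HashEmbedder(8, 3))

    def test_log_transform_beats_raw_fit_on_lognormal_data(self):
        ds = make_reaction_dataset(
            SyntheticReactionSpec(
                n_reported=400, n_random=0, separation=0.0, kcat_noise_sd=0.5, seed=21
            )
        )
        logged = train_kcat(ds.records, ds.substrate_embedder, ds.enzyme_embedder, seed=0)
        raw = train_kcat(
            ds.records, ds.substrate_embedder, ds.enzyme_embedder, seed=0,
            log_transform=False,
        )
        assert logged.mse < raw.mse

    def test_prediction_on_log_scale(self):
        ds = make_reaction_dataset(
            SyntheticReactionSpec(n_reported=200, n_random=0, kcat_noise_sd=0.0, seed=3)
        )
        model = train_kcat(ds.records, ds.substrate_embedder, ds.enzyme_embedder, seed=0)
        pred = predict_kcat_log(
            model, ds.records[0], ds.substrate_embedder, ds.enzyme_embedder
        )
        true_log = np.log10(ds.records[0].kcat)
        assert abs(pred - true_log) < 2.0  # log-scale prediction, not raw s^-1


class TestDeltaStats:
    @pytest.mark.parametrize(
        "wt, mut, expected",
        [(0.4, 0.9, 0.5), (0.7, 0.7, 0.0), (0.9, 0.4, -0.5)],
    )
    def test_sign_convention(self, wt, mut, expected):
        (stat,) = delta_scores({"r1": wt}, {"r1": mut})
        assert stat.delta == pytest.approx(expected)

    def test_unpaired_ids_rejected(self):
        with pytest.raises(ValueError, match="unpaired"):
            delta_scores({"r1": 0.1}, {"r2": 0.2})

    def test_dataclass_identity(self):
        d = DeltaStat(reaction_id="r", x_wt=0.25, x_mutant=0.75)
        assert d.delta == 0.5


class TestSplitByMedian:
    def test_even_split(self):
        low, high = split_by_median({"a": 1, "b": 2, "c": 3, "d": 4})
        assert sorted(low.values()) == [1, 2]
        assert sorted(high.values()) == [3, 4]

    def test_all_equal_go_high(self):
        low, high = split_by_median({"a": 5, "b": 5, "c": 5})
        assert low == {} and len(high) == 3

    def test_singleton_rejected(self):
        with pytest.raises(ValueError):
            split_by_median({"a": 7})


def _brute_force_mwu_two_sided(a, b):
    """Enumerate all group assignments of the pooled values."""
    pooled = list(a) + list(b)
    na = len(a)

    def u_stat(group_a, group_b):
        return sum(
            1.0 if x > y else (0.5 if x == y else 0.0) for x in group_a for y in group_b
        )

    u_obs = u_stat(a, b)
    mean = na * len(b) / 2.0
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), na):
        ga = [pooled[i] for i in idx]
        gb = [pooled[i] for i in range(len(pooled)) if i not in idx]
        total += 1
        if abs(u_stat(ga, gb) - mean) >= abs(u_obs - mean) - 1e-12:
            count += 1
    return u_obs, count / total


class TestMannWhitneyU:
    def test_textbook_example(self):
        u, p = mann_whitney_u([1, 2], [3, 4])
        assert u == 0.0
        assert p == pytest.approx(1 / 3)

    def test_identical_groups_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0, abs=0.02)

    def test_complete_separation(self):
        u, _ = mann_whitney_u(list(range(1, 6)), list(range(10, 15)))
        assert u == 0.0

    def test_exact_branch_matches_enumeration(self):
        rng = np.random.default_rng(77)
        for _ in range(20):
            na = int(rng.integers(1, 5))
            nb = int(rng.integers(1, 5))
            vals = rng.permutation(20)[: na + nb].astype(float)  # distinct -> no ties
            a, b = list(vals[:na]), list(vals[na:])
            u, p = mann_whitney_u(a, b)
            u_bf, p_bf = _brute_force_mwu_two_sided(a, b)
            assert u == pytest.approx(u_bf)
            assert p == pytest.approx(p_bf)

    def test_exact_branch_matches_scipy_exact(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = list(rng.normal(size=4))
            b = list(rng.normal(size=5))
            u, p = mann_whitney_u(a, b)
            res = scipy_mwu(a, b, alternative="two-sided", method="exact")
            assert u == pytest.approx(res.statistic)
            assert p == pytest.approx(res.pvalue)

    def test_asymptotic_branch_matches_scipy(self):
        rng = np.random.default_rng(6)
        a = list(np.round(rng.normal(size=30), 1))  # rounding forces ties
        b = list(np.round(rng.normal(0.5, size=25), 1))
        u, p = mann_whitney_u(a, b)
        res = scipy_mwu(a, b, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(res.statistic)
        assert p == pytest.approx(res.pvalue, rel=1e-6)

    @pytest.mark.parametrize("alternative", ["less", "greater"])
    def test_one_sided_consistency(self, alternative):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        _, p = mann_whitney_u(a, b, alternative=alternative)
        res = scipy_mwu(a, b, alternative=alternative, method="exact")
        assert p == pytest.approx(res.pvalue)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])
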