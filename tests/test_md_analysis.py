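"""Dihedral-deviation statistic, correlations, and control mutants."""

import numpy as np
import pytest

from enzopt.core_sequences import ProteinSequence, hamming_distance, make_mutant_record
from enzopt.md_analysis import (
    DihedralTrajectory,
    HelixAnnotation,
    angular_difference,
    dihedral_correlations,
    f_sim,
    f_sim_profile,
    make_proline_control,
    make_random_controls,
    read_dihedral_table,
    write_dihedral_table,
)
from enzopt.synthetic_data import (
    Perturbation,
    SyntheticTrajectorySpec,
    make_trajectory_pair,
)


def _traj(angles, kind="phi", spacing=100.0):
    angles = np.atleast_2d(np.asarray(angles, dtype=float))
    n_res, n_snap = angles.shape
    return DihedralTrajectory(
        angle_kind=kind,
        snapshot_times=np.arange(n_snap) * spacing,
        angles=angles,
        residue_ids=list(range(1, n_res + 1)),
    )


def _naive_f_sim(wt, mut, t_prime, variant):
    """Double-loop oracle transcribing the statistic term by term."""
    t_max = wt.angles.shape[1] - 1
    total = 0.0
    for t in range(t_prime, t_max + 1):
        for i in range(wt.angles.shape[0]):
            ref = wt.angles[i, t_prime] if variant == "printed" else wt.angles[i, t]
            d = angular_difference(ref, mut.angles[i, t])
            total += d * d
    return total / ((t_max - t_prime) * wt.angles.shape[0])


class TestAngularDifference:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(10, 10, 0.0), (170, -170, -20.0), (-180, 180, 0.0), (-170, 170, 20.0)],
    )
    def test_examples(self, a, b, expected):
        assert angular_difference(a, b) == pytest.approx(expected)

    def test_range_is_half_open_at_minus_180(self):
        assert angular_difference(0, 180) == pytest.approx(180.0)


class TestFSim:
    def test_identical_constant_trajectories_are_zero(self):
        wt = _traj([[10, 10, 10]])
        for tp in (0, 1):
            assert f_sim(wt, wt, tp) == 0.0

    def test_hand_example(self):
        # 1 residue, wt constant 10, mutant 10/20/40, t' = first snapshot:
        # (0 + 100 + 900) / (2 * 1) = 500
        wt = _traj([[10, 10, 10]])
        mut = _traj([[10, 20, 40]])
        assert f_sim(wt, mut, 0) == pytest.approx(500.0)

    def test_quadratic_homogeneity(self):
        wt = _traj([[0, 0, 0, 0]])
        mut1 = _traj([[0, 5, 10, 15]])
        mut2 = _traj([[0, 10, 20, 30]])
        assert f_sim(wt, mut2, 0) == pytest.approx(4 * f_sim(wt, mut1, 0))

    def test_matches_naive_oracle_both_variants(self, rng):
        for _ in range(50):
            n_res = int(rng.integers(1, 6))
            n_snap = int(rng.integers(2, 11))
            wt = _traj(rng.uniform(-180, 180, size=(n_res, n_snap)))
            mut = _traj(rng.uniform(-180, 180, size=(n_res, n_snap)))
            tp = int(rng.integers(0, n_snap - 1))
            for variant in ("printed", "time-matched"):
                assert f_sim(wt, mut, tp, variant) == pytest.approx(
                    _naive_f_sim(wt, mut, tp, variant), abs=1e-9
                )

    def test_common_rotation_invariance(self, rng):
        base = rng.uniform(-60, 60, size=(3, 8))
        offs = rng.uniform(-30, 30, size=(3, 8))
        wt, mut = _traj(base), _traj(base + offs)
        shift = 150.0  # pushes many angles across the seam
        wrap = lambda a: (a + 180.0) % 360.0 - 180.0
        wt_s, mut_s = _traj(wrap(base + shift)), _traj(wrap(base + offs + shift))
        for tp in (0, 3):
            assert f_sim(wt_s, mut_s, tp) == pytest.approx(f_sim(wt, mut, tp))

    def test_last_snapshot_excluded(self):
        wt = _traj([[0, 0, 0]])
        with pytest.raises(ValueError):
            f_sim(wt, wt, 2)

    def test_grid_mismatch_rejected(self):
        wt = _traj([[0, 0, 0]])
        mut = _traj([[0, 0, 0, 0]])
        with pytest.raises(ValueError):
            f_sim(wt, mut, 0)


class TestFSimProfile:
    def test_identical_constant_trajectories_all_zero(self):
        # the default variant freezes the WT at t', so only a pair that is
        # identical AND constant in time gives a uniformly zero profile
        wt = _traj([np.full(30, 12.0)])
        profile = f_sim_profile(wt, wt, window_ns=None)
        assert (profile["f_sim"] == 0).all()
        assert len(profile) == 29

    def test_identical_trajectories_zero_under_time_matching(self):
        wt = _traj([np.linspace(-50, 50, 30)])
        profile = f_sim_profile(wt, wt, window_ns=None, variant="time-matched")
        assert (profile["f_sim"] == 0).all()

    def test_window_selects_trailing_snapshots(self):
        wt = _traj([np.zeros(50)])
        profile = f_sim_profile(wt, wt, window_ns=2.0)  # 2 ns = 20 snapshots @ 100 ps
        assert profile["t_prime"].iloc[0] == 29  # times 2900..4800 admissible
        assert len(profile) == 20

    def test_late_perturbation_raises_late_f_sim(self):
        quiet = SyntheticTrajectorySpec(n_residues=5, n_snapshots=40, seed=3)
        shaken = SyntheticTrajectorySpec(
            n_residues=5,
            n_snapshots=40,
            seed=3,
            perturbation=Perturbation(residues=(2, 3), time_window=(30, 39), amplitude_deg=90.0),
        )
        wt_q, mut_q = make_trajectory_pair(quiet)
        wt_s, mut_s = make_trajectory_pair(shaken)
        prof_q = f_sim_profile(wt_q, mut_q, window_ns=None)
        prof_s = f_sim_profile(wt_s, mut_s, window_ns=None)
        late = prof_s["t_prime"] >= 30
        assert prof_s.loc[late, "f_sim"].mean() > prof_q.loc[late, "f_sim"].mean()


class TestDihedralCorrelations:
    def test_identical_series_correlate_perfectly(self):
        wt = _traj(np.vstack([np.linspace(-30, 30, 10), np.sin(np.arange(10)) * 20]))
        summary = dihedral_correlations(wt, wt)
        assert all(r == pytest.approx(1.0) for r in summary.per_residue.values())

    def test_mirrored_fluctuations_anticorrelate(self):
        series = np.linspace(-40, 40, 12)
        wt = _traj([series])
        mut = _traj([-series])
        summary = dihedral_correlations(wt, mut)
        assert summary.per_residue[1] == pytest.approx(-1.0)

    def test_linear_scaling_gives_perfect_correlation(self):
        wt = _traj([[0, 10, 20]])
        mut = _traj([[0, 20, 40]])
        assert dihedral_correlations(wt, mut).per_residue[1] == pytest.approx(1.0)

    def test_zero_variance_residue_skipped_with_warning(self):
        wt = _traj([[0, 0, 0, 0], [0, 10, 20, 30]])
        mut = _traj([[1, 2, 3, 4], [0, 10, 20, 31]])
        with pytest.warns(UserWarning, match="zero-variance"):
            summary = dihedral_correlations(wt, mut)
        assert summary.skipped_residues == [1]
        assert 2 in summary.per_residue

    def test_too_few_snapshots_rejected(self):
        wt = _traj([[0, 10]])
        with pytest.raises(ValueError):
            dihedral_correlations(wt, wt)


class TestRandomControls:
    def test_controls_mutate_exactly_the_best_positions(self, rng):
        wt = ProteinSequence(id="wt", residues="MKTAYIAKQR")
        best_seq = ProteinSequence(id="best", residues="MATAYIGKQR")
        best = make_mutant_record(wt, best_seq)
        controls = make_random_controls(wt, best, n=5, rng=rng)
        assert len(controls) == 5
        best_positions = {m.position for m in best.mutations}
        for c in controls:
            assert {m.position for m in c.mutations} == best_positions
            for m in c.mutations:
                best_at = next(b for b in best.mutations if b.position == m.position)
                assert m.new_residue != best_at.new_residue
                assert m.new_residue != m.wt_residue

    def test_reproducible_per_seed(self):
        wt = ProteinSequence(id="wt", residues="MKTAYIAKQR")
        best = make_mutant_record(wt, ProteinSequence(id="b", residues="MATAYIAKQR"))
        a = make_random_controls(wt, best, n=3, rng=7)
        b = make_random_controls(wt, best, n=3, rng=7)
        assert [c.sequence.residues for c in a] == [c.sequence.residues for c in b]

    def test_mutationless_best_rejected(self):
        wt = ProteinSequence(id="wt", residues="MKT")
        with pytest.raises(ValueError):
            make_random_controls(wt, make_mutant_record(wt, wt), n=2)


class TestProlineControl:
    def test_prolines_inside_annotated_helix(self):
        wt = ProteinSequence(id="wt", residues="MKTAYIAKQRWA")
        control = make_proline_control(wt, HelixAnnotation(ranges=((4, 10),)), rng=0)
        s = control.sequence.residues
        assert "PPPPP" in s
        start = s.index("PPPPP") + 1
        assert 4 <= start and start + 4 <= 10
        assert len(s) == len(wt)

    def test_exact_length_helix_has_unique_placement(self):
        wt = ProteinSequence(id="wt", residues="MKTAYIAKQRWA")
        for seed in range(5):
            control = make_proline_control(wt, HelixAnnotation(ranges=((5, 9),)), rng=seed)
            assert control.sequence.residues[4:9] == "PPPPP"

    def test_no_eligible_helix_rejected(self):
        wt = ProteinSequence(id="wt", residues="MKTAYIAKQR")
        with pytest.raises(ValueError):
            make_proline_control(wt, HelixAnnotation(ranges=((2, 4),)), rng=0)

    def test_existing_prolines_not_recounted_as_mutations(self):
        wt = ProteinSequence(id="wt", residues="MKPAYIAKQR")
        control = make_proline_control(wt, HelixAnnotation(ranges=((1, 10),)), rng=1)
        assert hamming_distance(wt, control.sequence) == len(control.mutations)


class TestTrajectoryValidation:
    def test_nonuniform_spacing_rejected(self):
        with pytest.raises(ValueError, match="uniform"):
            DihedralTrajectory(
                angle_kind="phi",
                snapshot_times=np.array([0.0, 100.0, 250.0]),
                angles=np.zeros((1, 3)),
                residue_ids=[1],
            )

    def test_out_of_range_angles_rejected(self):
        with pytest.raises(ValueError, match="degrees"):
            DihedralTrajectory(
                angle_kind="phi",
                snapshot_times=np.array([0.0, 100.0]),
                angles=np.array([[0.0, 181.0]]),
                residue_ids=[1],
            )


class TestDihedralIO:
    def test_tsv_round_trip(self, tmp_path):
        spec = SyntheticTrajectorySpec(n_residues=4, n_snapshots=6, seed=2)
        phi_wt, _ = make_trajectory_pair(spec)
        psi_spec = SyntheticTrajectorySpec(n_residues=4, n_snapshots=6, angle_kind="psi", seed=3)
        psi_wt, _ = make_trajectory_pair(psi_spec)
        path = tmp_path / "traj.tsv"
        write_dihedral_table(phi_wt, psi_wt, path)
        back = read_dihedral_table(path)
        np.testing.assert_allclose(back["phi"].angles, phi_wt.angles)
        np.testing.assert_allclose(back["psi"].angles, psi_wt.angles)
        np.testing.assert_allclose(back["phi"].snapshot_times, phi_wt.snapshot_times)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("time_ps\tresidue\tphi_deg\n0\t1\t10\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_dihedral_table(path)
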