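"""The solute-split pair procedure and the condensed RMSD matrix."""

import numpy as np
import pytest

from solvclust.geometry import weighted_rmsd
from solvclust.pairdist import (
    CondensedRMSDMatrix,
    PairOptions,
    direct_min_rmsd,
    load_matrix,
    matrix_sum,
    pair_min_rmsd,
    rmsd_matrix,
    save_matrix,
)
from solvclust.synthetic import (
    FixtureSpec,
    make_clustered_trajectory,
    make_congruent_pair,
)
from solvclust.traj_io import SoluteSpec, Snapshot, Trajectory

from conftest import global_min_rmsd_oracle, one_solute_two_waters


def opts_for(ns, alg="hungarian", **kw):
    return PairOptions(spec=SoluteSpec(n_solute=ns), reorder_alg=alg, **kw)


class TestPairMinRMSD:
    @pytest.mark.parametrize("alg", ["hungarian", "hungarian_inertia", "brute"])
    def test_congruent_pair_is_zero(self, alg):
        A, B, ns = make_congruent_pair(FixtureSpec(n_solvent=3, rng_seed=2))
        assert pair_min_rmsd(A, B, opts_for(ns, alg)) < 1e-8

    def test_naive_rmsd_of_congruent_pair_is_large(self):
        A, B, _ = make_congruent_pair(FixtureSpec(n_solvent=3, rng_seed=2))
        assert weighted_rmsd(A.coords, B.coords) > 0.5

    def test_self_distance_is_zero(self):
        A, _, ns = make_congruent_pair(FixtureSpec(rng_seed=4))
        assert pair_min_rmsd(A, A, opts_for(ns)) < 1e-12

    def test_never_exceeds_raw_rmsd(self, rng):
        for seed in range(10):
            A, B, ns = make_congruent_pair(
                FixtureSpec(rng_seed=seed, rotate=False)
            )
            raw = weighted_rmsd(A.coords, B.coords)
            assert pair_min_rmsd(A, B, opts_for(ns)) <= raw + 1e-12

    def test_composition_mismatch_errors(self):
        a = Snapshot(("O", "H"), np.zeros((2, 3)))
        b = Snapshot(("O", "O"), np.zeros((2, 3)))
        with pytest.raises(ValueError, match="composition"):
            pair_min_rmsd(a, b, opts_for(1))

    def test_brute_matches_exhaustive_oracle(self):
        """1 solute + 2 rigid waters, random perturbation: the staged
        brute result equals the global permutation x rotation minimum."""
        for seed in range(10):
            elements, A, B = one_solute_two_waters(seed)
            oracle = global_min_rmsd_oracle(A, B, elements, 1)
            ours = pair_min_rmsd(
                A, B, opts_for(1, "brute"), elements=elements
            )
            assert ours == pytest.approx(oracle, abs=1e-9)

    def test_brute_is_symmetric(self):
        for seed in range(5):
            elements, A, B = one_solute_two_waters(seed)
            o = opts_for(1, "brute")
            dab = pair_min_rmsd(A, B, o, elements=elements)
            dba = pair_min_rmsd(B, A, o, elements=elements)
            assert abs(dab - dba) < 1e-8

    def test_split_beats_direct_on_most_fixtures(self):
        """The staged solute-first strategy should match or beat the
        single-stage joint reorder+Kabsch on at least 90% of random
        solvated congruent pairs."""
        wins = 0
        n = 50
        for seed in range(n):
            A, B, ns = make_congruent_pair(FixtureSpec(rng_seed=seed))
            split = pair_min_rmsd(A, B, opts_for(ns))
            direct = direct_min_rmsd(A, B)
            if split <= direct + 1e-9:
                wins += 1
        assert wins >= 0.9 * n

    def test_aligned_coordinates_returned(self):
        A, B, ns = make_congruent_pair(FixtureSpec(n_solvent=2, rng_seed=9))
        r, aligned = pair_min_rmsd(A, B, opts_for(ns), return_aligned=True)
        assert aligned.shape == A.coords.shape
        # aligned B reproduces A up to the reported RMSD (same weights)
        assert weighted_rmsd(A.coords, aligned) == pytest.approx(r, abs=1e-8)


class TestMatrix:
    def test_identical_frames_all_zero(self):
        A, _, ns = make_congruent_pair(FixtureSpec(n_solvent=2, rng_seed=1))
        traj = Trajectory([Snapshot(A.elements, A.coords, i) for i in range(3)])
        m = rmsd_matrix(traj, opts_for(ns))
        np.testing.assert_allclose(m.d, 0.0, atol=1e-10)

    def test_condensed_length(self):
        traj, _, ns = make_clustered_trajectory(
            FixtureSpec(n_frames=4, n_solvent=2, rng_seed=3)
        )
        m = rmsd_matrix(traj, opts_for(ns))
        assert m.d.shape == (6,)

    def test_worker_count_does_not_change_bits(self):
        traj, _, ns = make_clustered_trajectory(
            FixtureSpec(n_frames=10, n_solvent=2, rng_seed=8)
        )
        m1 = rmsd_matrix(traj, opts_for(ns), n_workers=1)
        m4 = rmsd_matrix(traj, opts_for(ns), n_workers=4)
        np.testing.assert_array_equal(m1.d, m4.d)

    def test_repeated_runs_identical(self):
        traj, _, ns = make_clustered_trajectory(
            FixtureSpec(n_frames=6, n_solvent=2, rng_seed=8)
        )
        m1 = rmsd_matrix(traj, opts_for(ns))
        m2 = rmsd_matrix(traj, opts_for(ns))
        np.testing.assert_array_equal(m1.d, m2.d)

    def test_cache_round_trip_and_fingerprint(self, tmp_path):
        traj, _, ns = make_clustered_trajectory(
            FixtureSpec(n_frames=5, n_solvent=2, rng_seed=8)
        )
        cache = tmp_path / "m.cache"
        opts = opts_for(ns)
        m = rmsd_matrix(traj, opts, cache_path=cache)
        again = rmsd_matrix(traj, opts, cache_path=cache)
        np.testing.assert_array_equal(m.d, again.d)
        # stale cache (different options) is refused without force
        other = opts_for(ns, "distance")
        with pytest.raises(ValueError, match="fingerprint"):
            rmsd_matrix(traj, other, cache_path=cache)
        forced = rmsd_matrix(traj, other, cache_path=cache, force=True)
        assert forced.d.shape == m.d.shape

    def test_matrix_save_load(self, tmp_path):
        m = CondensedRMSDMatrix(np.array([1.0, 2.0, 3.0]), 3)
        save_matrix(m, tmp_path / "x.cache", "fp")
        back = load_matrix(tmp_path / "x.cache", expect_fingerprint="fp")
        np.testing.assert_array_equal(back.d, m.d)
        assert back.M == 3

    def test_indexing(self):
        m = CondensedRMSDMatrix(np.array([1.0, 2.0, 3.0]), 3)
        assert m[0, 1] == 1.0
        assert m[2, 0] == 2.0
        assert m[1, 2] == 3.0
        sq = m.squareform()
        assert sq[0, 1] == 1.0 and sq[1, 0] == 1.0


class TestMatrixSum:
    def test_zero_matrix(self):
        assert matrix_sum(CondensedRMSDMatrix(np.zeros(3), 3)) == 0.0

    def test_simple_entries(self):
        assert matrix_sum(CondensedRMSDMatrix(np.array([1.0, 2, 3]), 3)) == 6.0

    def test_matches_explicit_pair_loop(self):
        traj, _, ns = make_clustered_trajectory(
            FixtureSpec(n_frames=6, n_solvent=2, rng_seed=13)
        )
        opts = opts_for(ns)
        m = rmsd_matrix(traj, opts)
        total = 0.0
        for i in range(6):
            for j in range(i + 1, 6):
                total += pair_min_rmsd(traj[i], traj[j], opts)
        assert matrix_sum(m) == pytest.approx(total)


def test_unknown_reorder_algorithm_rejected():
    with pytest.raises(ValueError, match="reorder"):
        PairOptions(spec=SoluteSpec(n_solute=1), reorder_alg="qml")
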