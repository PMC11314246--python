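import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from pepsurf import clustering


def oracle_min_rmsd(A, B, n_grid=4000, seed=0):
    """Brute-force rotation search (random grid + simplex refinement),
    independent of the Kabsch route."""
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)

    def rmsd_of_rotation(quat):
        R = Rotation.from_quat(quat / np.linalg.norm(quat)).as_matrix()
        return np.sqrt(np.mean(np.sum((A - B @ R.T) ** 2, axis=1)))

    quats = Rotation.random(n_grid, random_state=seed).as_quat()
    vals = [rmsd_of_rotation(q) for q in quats]
    best = quats[int(np.argmin(vals))]
    res = minimize(rmsd_of_rotation, best, method="Nelder-Mead",
                   options=dict(xatol=1e-10, fatol=1e-12, maxiter=5000))
    return float(res.fun)


def oracle_daura(D, cutoff):
    """Independent greedy re-implementation on a distance matrix."""
    F = len(D)
    remaining = set(range(F))
    assignments = {}
    centers = []
    cid = 0
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if D[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(remaining) if D[best][j] <= cutoff]
        for j in members:
            assignments[j] = cid
        centers.append(best)
        remaining -= set(members)
        cid += 1
    return assignments, centers


class TestKabschRmsd:
    def test_self_is_zero(self):
        A = np.random.default_rng(0).normal(size=(8, 3))
        assert clustering.kabsch_rmsd(A, A) == pytest.approx(0.0, abs=1e-6)

    def test_rigid_motion_invariance(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(8, 3))
        R = Rotation.random(random_state=2).as_matrix()
        B = A @ R.T + np.array([3.0, -4.0, 5.0])
        assert clustering.kabsch_rmsd(A, B) < 1e-6

    def test_mismatched_shapes_rejected(self):
        with pytest.raises(ValueError):
            clustering.kabsch_rmsd(np.zeros((4, 3)), np.zeros((5, 3)))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_rotation_search(self, seed):
        rng = np.random.default_rng(seed)
        A = rng.normal(size=(4, 3))
        B = rng.normal(size=(4, 3))
        ours = clustering.kabsch_rmsd(A, B)
        brute = oracle_min_rmsd(A, B, seed=seed)
        assert ours == pytest.approx(brute, abs=1e-4)
        assert ours <= brute + 1e-9  # ours is the true minimum

    def test_matches_mdanalysis(self):
        from MDAnalysis.analysis.rms import rmsd as mda_rmsd

        rng = np.random.default_rng(3)
        for _ in range(10):
            A = rng.normal(size=(12, 3))
            B = rng.normal(size=(12, 3))
            assert clustering.kabsch_rmsd(A, B) == pytest.approx(
                mda_rmsd(A, B, center=True, superposition=True), abs=1e-9
            )

    def test_pairwise_matrix_matches_single_pairs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 6, 3))
        D = clustering.pairwise_rmsd(X)
        for i in range(12):
            for j in range(12):
                assert D[i, j] == pytest.approx(
                    clustering.kabsch_rmsd(X[i], X[j]), abs=1e-6
                )


class TestDauraCluster:
    def test_identical_frames_single_cluster(self):
        X = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (10, 1, 1))
        res = clustering.daura_cluster(X, cutoff=1.0)
        assert res.n_conf == 1
        assert res.populations[0] == 1.0

    def test_all_far_apart_singletons(self):
        # distinct internal geometries (pure translations would superpose)
        rng = np.random.default_rng(1)
        X = np.array([rng.normal(size=(5, 3)) * (1 + 5 * k) for k in range(6)])
        res = clustering.daura_cluster(X, cutoff=0.5)
        assert res.n_conf == 6
        np.testing.assert_allclose(res.populations, 1 / 6)

    def test_every_frame_within_cutoff_of_center(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 6, 3))
        cutoff = 1.2
        res = clustering.daura_cluster(X, cutoff=cutoff)
        D = clustering.pairwise_rmsd(X)
        for f, cid in enumerate(res.assignments):
            assert D[res.centers[cid], f] <= cutoff + 1e-9

    def test_rotation_translation_invariance(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(25, 6, 3))
        res1 = clustering.daura_cluster(X, cutoff=1.2)
        R = Rotation.random(random_state=4).as_matrix()
        X2 = X @ R.T + np.array([10.0, 0.0, -7.0])
        res2 = clustering.daura_cluster(X2, cutoff=1.2)
        np.testing.assert_array_equal(res1.assignments, res2.assignments)

    def test_cutoff_monotonicity(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(30, 6, 3))
        n = [
            clustering.daura_cluster(X, cutoff=c).n_conf
            for c in (0.5, 0.8, 1.1, 1.4, 2.0)
        ]
        assert all(a >= b for a, b in zip(n, n[1:]))


class TestEntropy:
    def test_single_cluster_zero(self):
        assert clustering.conformational_entropy([1.0]) == 0.0

    def test_uniform_is_log_n(self):
        p = np.full(263, 1 / 263)
        assert clustering.conformational_entropy(p) == pytest.approx(np.log(263), abs=1e-9)

    def test_half_half(self):
        assert clustering.conformational_entropy([0.5, 0.5]) == pytest.approx(
            np.log(2), abs=1e-12
        )

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            clustering.conformational_entropy([1.2, -0.2])

    def test_not_normalized_rejected(self):
        with pytest.raises(ValueError):
            clustering.conformational_entropy([0.3, 0.3])

    @given(st.lists(st.floats(0.01, 10.0), min_size=1, max_size=50))
    @settings(deadline=None, max_examples=50)
    def test_bounds(self, weights):
        p = np.array(weights) / np.sum(weights)
        s = clustering.conformational_entropy(p)
        assert -1e-9 <= s <= np.log(len(p)) + 1e-9


class TestCombinedOverlap:
    def test_duplicated_trajectory_full_overlap(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(30, 6, 3))
        _, overlap = clustering.combined_overlap({"a": X, "b": X.copy()}, cutoff=1.0)
        assert overlap == pytest.approx(1.0)

    def test_disjoint_ensembles_zero_overlap(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(20, 6, 3))
        B = rng.normal(size=(20, 6, 3)) * 10
        _, overlap = clustering.combined_overlap({"a": A, "b": B}, cutoff=0.8)
        assert overlap == pytest.approx(0.0)

    def test_planted_shared_fraction_recovered(self):
        # two systems share three conformations carrying 30% of system B
        rng = np.random.default_rng(2)
        lib = rng.normal(size=(9, 8, 3)) * np.arange(1, 10)[:, None, None]
        pA = [0.15, 0.15, 0.15, 0.55, 0.0, 0.0, 0.0, 0.0, 0.0]
        pB = [0.10, 0.10, 0.10, 0.0, 0.35, 0.35, 0.0, 0.0, 0.0]
        n = 600

        def sample(p, seed):
            r = np.random.default_rng(seed)
            idx = r.choice(9, size=n, p=p)
            return lib[idx] + r.normal(0, 0.01, size=(n, 8, 3))

        _, overlap = clustering.combined_overlap(
            {"a": sample(pA, 3), "b": sample(pB, 4)}, cutoff=1.0
        )
        se = np.sqrt(3 * 0.1 * 0.9 / n)
        assert abs(overlap - 0.3) < 3 * se

    def test_single_trajectory_rejected(self):
        with pytest.raises(ValueError):
            clustering.combined_overlap({"a": np.zeros((3, 4, 3))})

    def test_incompatible_topologies_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            clustering.combined_overlap(
                {"a": np.zeros((3, 4, 3)), "b": np.zeros((3, 5, 3))}
            )


class TestEquilibration:
    def test_threshold_ratio_at_300K(self):
        # exp(-2 / (kB * 300)) with kB = 0.0019872041 kcal/mol/K
        assert clustering.low_free_energy_threshold(300.0, 2.0) == pytest.approx(
            0.0349, abs=5e-5
        )

    def test_single_conformation_constant_curve(self):
        X = np.tile(np.random.default_rng(0).normal(size=(5, 3)), (30, 1, 1))
        curve = clustering.equilibration_curve(X, n_windows=5)
        assert (curve["n_low_free_energy"] == 1).all()

    def test_stationary_ensemble_plateaus(self):
        rng = np.random.default_rng(1)
        lib = rng.normal(size=(4, 6, 3)) * np.arange(1, 5)[:, None, None]
        idx = rng.choice(4, size=400)
        X = lib[idx] + rng.normal(0, 0.01, size=(400, 6, 3))
        curve = clustering.equilibration_curve(X, n_windows=8, cutoff=1.0)
        tail = curve["n_low_free_energy"].iloc[-2:]
        assert tail.iloc[0] == tail.iloc[1]

    def test_daura_against_oracle_small_instances(self):
        # acceptance-grade equivalence check at small n; more instances in
        # the acceptance suite
        rng = np.random.default_rng(9)
        for _ in range(10):
            X = rng.normal(size=(rng.integers(5, 15), 5, 3))
            D = clustering.pairwise_rmsd(X)
            cutoff = float(np.quantile(D[np.triu_indices(len(X), 1)], 0.4))
            res = clustering.daura_cluster(X, cutoff=cutoff, rmsd_matrix=D)
            oracle_assign, oracle_centers = oracle_daura(D, cutoff)
            assert list(res.centers) == oracle_centers
            assert [oracle_assign[f] for f in range(len(X))] == list(res.assignments)
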