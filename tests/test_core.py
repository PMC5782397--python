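"""Solver unit tests: objective, move costs, removal, convergence."""

import numpy as np
import pytest

from shrinkclust import (
    ShrinkageClustering,
    SolverState,
    best_move,
    compute_objective,
    delta_f,
    exact_recovery,
    initialize_partition,
    make_assignment,
    remove_small_clusters,
    shrinkage_cluster,
    similarity_from_assignment,
)
from shrinkclust.core import apply_move

from _oracles import all_partitions, brute_objective, frobenius_gap


class TestObjective:
    @pytest.mark.parametrize(
        "labels, expected",
        [
            ([0, 0, 1], -5.0),  # the optimal two-cluster split
            ([0, 0, 0], -1.0),  # everything merged
            ([0, 1, 2], -3.0),  # singletons: only self-pairs, each -1
        ],
    )
    def test_toy_values(self, toy_similarity, labels, expected):
        assert compute_objective(toy_similarity, labels) == pytest.approx(expected)

    def test_block_truth_closed_form(self, balanced_sizes):
        # noiseless S = AA^T at the truth: f = -sum n_k^2
        truth = make_assignment(balanced_sizes)
        S = similarity_from_assignment(truth)
        expected = -sum(n**2 for n in balanced_sizes)
        assert expected == -2066
        assert compute_objective(S, truth) == pytest.approx(expected)

    def test_singleton_partition_is_minus_n(self):
        rng = np.random.default_rng(1)
        S = rng.uniform(size=(7, 7))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        assert compute_objective(S, np.arange(7)) == pytest.approx(-7.0)

    def test_frobenius_identity(self):
        # f(A) + sum S_ij^2 == ||S - AA^T||_F^2 for random instances
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = int(rng.integers(2, 13))
            S = rng.uniform(size=(n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            labels = rng.integers(0, int(rng.integers(1, n + 1)), size=n)
            f = compute_objective(S, labels)
            assert f + (S**2).sum() == pytest.approx(frobenius_gap(S, labels), abs=1e-9)

    def test_dimension_mismatch_rejected(self, toy_similarity):
        with pytest.raises(ValueError):
            compute_objective(toy_similarity, [0, 1])


class TestDeltaF:
    def test_identity_move_is_zero(self, toy_similarity):
        state = SolverState(toy_similarity, [0, 0, 1])
        assert delta_f(state, 0, 0) == 0.0

    def test_worked_examples(self, toy_similarity):
        # merging object 2 into {0,1}: 2*((1-0)+(1-0) - 0) = 4
        state = SolverState(toy_similarity, [0, 0, 1])
        assert delta_f(state, 2, 0) == pytest.approx(4.0)
        # from singletons, moving object 0 next to its twin: 2*((1-2) - 0) = -2
        state = SolverState(toy_similarity, [0, 1, 2])
        assert delta_f(state, 0, 1) == pytest.approx(-2.0)

    def test_unknown_cluster_rejected(self, toy_similarity):
        state = SolverState(toy_similarity, [0, 0, 1])
        with pytest.raises(ValueError):
            delta_f(state, 0, 5)

    def test_matches_objective_difference(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n = int(rng.integers(3, 12))
            S = rng.uniform(size=(n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            k = int(rng.integers(2, n + 1))
            labels = rng.integers(0, k, size=n)
            state = SolverState(S, labels, n_clusters=k)
            i = int(rng.integers(0, n))
            target = int(rng.integers(0, k))
            before = brute_objective(S, labels)
            after_labels = labels.copy()
            after_labels[i] = target
            after = brute_objective(S, after_labels)
            assert delta_f(state, i, target) == pytest.approx(after - before, abs=1e-9)


class TestBestMove:
    def test_singleton_start_picks_lowest_index(self, toy_similarity):
        state = SolverState(toy_similarity, [0, 1, 2])
        # moves 0->1 and 1->0 tie at -2; ties resolve to object 0
        assert best_move(state) == (0, 1, pytest.approx(-2.0))

    def test_none_at_optimum(self, toy_similarity):
        state = SolverState(toy_similarity, [0, 0, 1])
        assert best_move(state) is None

    def test_single_object_single_cluster(self):
        state = SolverState(np.array([[1.0]]), [0])
        assert best_move(state) is None

    def test_agrees_with_exhaustive_scan(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            n = int(rng.integers(3, 10))
            S = rng.uniform(size=(n, n))
            S = (S + S.T) / 2
            np.fill_diagonal(S, 1.0)
            k = int(rng.integers(2, n + 1))
            labels = rng.integers(0, k, size=n)
            state = SolverState(S, labels, n_clusters=k)
            nonempty = np.flatnonzero(state.cluster_sizes > 0)
            candidates = [
                (i, c, delta_f(state, i, int(c)))
                for i in range(n)
                for c in nonempty
                if c != labels[i]
            ]
            got = best_move(state)
            if not candidates:
                assert got is None
                continue
            best = min(candidates, key=lambda t: (t[2], t[0], t[1]))
            if best[2] >= 0:
                assert got is None
            else:
                assert got[2] == pytest.approx(best[2])
                assert (got[0], got[1]) == (best[0], best[1])


class TestSolverState:
    def test_cluster_sums_match_brute_force_after_moves(self):
        rng = np.random.default_rng(3)
        S = rng.uniform(size=(9, 9))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        state = SolverState(S, rng.integers(0, 4, size=9), n_clusters=4)
        for _ in range(15):
            i = int(rng.integers(0, 9))
            c = int(rng.integers(0, state.k))
            apply_move(state, i, c)
            np.testing.assert_allclose(
                state.cluster_sums, state.brute_force_sums(), atol=1e-9
            )
        assert state.cluster_sizes.sum() == 9

    def test_negative_omega_rejected(self, toy_similarity):
        with pytest.raises(ValueError):
            SolverState(toy_similarity, [0, 0, 1], omega=-1)


class TestRemoveSmallClusters:
    def test_empty_clusters_dropped(self):
        S = similarity_from_assignment([0, 0, 0, 2, 2])
        state = SolverState(S, np.array([0, 0, 0, 2, 2]), n_clusters=3)
        remove_small_clusters(state)
        assert state.k == 2
        np.testing.assert_array_equal(np.sort(state.cluster_sizes), [2, 3])
        np.testing.assert_allclose(state.cluster_sums, state.brute_force_sums())

    def test_no_op_without_empty_clusters(self, toy_similarity):
        state = SolverState(toy_similarity, [0, 0, 1])
        labels_before = state.labels.copy()
        remove_small_clusters(state)
        assert state.k == 2
        np.testing.assert_array_equal(state.labels, labels_before)
        assert not state.removed_last_sweep

    def test_undersized_cluster_dissolved_by_affinity(self):
        # objects 0-3 alike, object 4 tied to them weakly: omega=2 dissolves
        # the singleton and folds it into the similar cluster
        truth = [0, 0, 0, 0, 1]
        S = similarity_from_assignment(truth).astype(float)
        S[3, 4] = S[4, 3] = 0.9
        state = SolverState(S, np.array([0, 0, 0, 0, 1]), n_clusters=2, omega=2)
        remove_small_clusters(state)
        assert state.k == 1
        assert state.cluster_sizes[0] == 5
        np.testing.assert_allclose(state.cluster_sums, state.brute_force_sums())

    def test_single_undersized_cluster_retained_with_warning(self):
        S = similarity_from_assignment([0, 0, 0])
        state = SolverState(S, np.array([0, 0, 0]), n_clusters=1, omega=10)
        with pytest.warns(UserWarning, match="cannot be met"):
            remove_small_clusters(state)
        assert state.k == 1


class TestInitialization:
    def test_reproducible_and_in_range(self):
        a = initialize_partition(100, 20, seed=5)
        b = initialize_partition(100, 20, seed=5)
        np.testing.assert_array_equal(a, b)
        assert a.shape == (100,)
        assert a.min() >= 0 and a.max() < 20

    @pytest.mark.parametrize("k0", [0, 101])
    def test_k0_out_of_range(self, k0):
        with pytest.raises(ValueError):
            initialize_partition(100, k0, seed=0)


class TestSolver:
    def test_toy_unique_optimum(self, toy_similarity):
        # exhaustive enumeration: f = -5 at {0,1},{2} is the unique minimum
        best = min(
            all_partitions(3), key=lambda lab: brute_objective(toy_similarity, lab)
        )
        assert brute_objective(toy_similarity, best) == -5.0
        for seed in range(10):
            res = shrinkage_cluster(toy_similarity, k0=3, seed=seed, restarts=3)
            assert res.k_final == 2
            assert res.objective == pytest.approx(-5.0)
            assert res.labels[0] == res.labels[1] != res.labels[2]
            assert res.converged

    def test_noiseless_block_recovery(self, balanced_sizes):
        truth = make_assignment(balanced_sizes)
        S = similarity_from_assignment(truth)
        res = shrinkage_cluster(S, k0=20, seed=0)
        assert res.k_final == 5
        assert exact_recovery(truth, res.labels)

    def test_path_invariants(self, balanced_sizes):
        truth = make_assignment(balanced_sizes)
        S = similarity_from_assignment(truth)
        res = shrinkage_cluster(S, k0=20, seed=3)
        ks = res.path[:, 1]
        assert (np.diff(ks) <= 0).all()  # clusters only ever disappear
        fs = res.path[:, 2]
        diffs = np.diff(fs)
        nonzero = np.flatnonzero(diffs != 0)
        if nonzero.size:  # strict decrease at move steps, flat only at the tail
            assert (diffs[: nonzero.max() + 1] < 0).all()
        assert res.objective >= -(S**2).sum() - 1e-9

    def test_restarts_return_best_objective(self, toy_similarity):
        singles = [
            shrinkage_cluster(toy_similarity, k0=3, seed=10 + r).objective
            for r in range(5)
        ]
        multi = shrinkage_cluster(toy_similarity, k0=3, seed=10, restarts=5)
        assert multi.objective == pytest.approx(min(singles))

    def test_max_iter_exhaustion_flagged(self, balanced_sizes):
        S = similarity_from_assignment(make_assignment(balanced_sizes))
        res = shrinkage_cluster(S, k0=20, seed=0, max_iter=3)
        assert not res.converged
        assert res.n_iterations == 3

    def test_single_object(self):
        res = shrinkage_cluster(np.array([[1.0]]))
        assert res.k_final == 1 and res.converged

    def test_all_ones_similarity_collapses_to_one_cluster(self):
        S = np.ones((12, 12))
        res = shrinkage_cluster(S, k0=6, seed=2)
        assert res.k_final == 1

    def test_size_floor_enforced(self, balanced_sizes):
        truth = make_assignment(balanced_sizes)
        S = similarity_from_assignment(truth)
        for omega, seed in [(20, 0), (25, 1), (40, 2)]:
            res = shrinkage_cluster(S, k0=20, omega=omega, seed=seed)
            assert res.cluster_sizes.min() >= omega

    def test_global_optimum_on_tiny_blocks(self):
        # exhaustive enumeration over all set partitions of 8 objects
        truth = make_assignment([3, 3, 2])
        S = similarity_from_assignment(truth)
        best = min(brute_objective(S, lab) for lab in all_partitions(8))
        res = shrinkage_cluster(S, k0=8, seed=0, restarts=10)
        assert res.objective == pytest.approx(best)
        assert exact_recovery(truth, res.labels)

    def test_invalid_inputs(self, toy_similarity):
        with pytest.raises(ValueError):
            shrinkage_cluster(toy_similarity, restarts=0)
        with pytest.raises(ValueError):
            shrinkage_cluster(np.ones((2, 3)))


class TestModelInterface:
    def test_fit_matches_function(self, toy_similarity):
        res = ShrinkageClustering(toy_similarity).fit(k0=3, seed=0, restarts=3)
        fun = shrinkage_cluster(toy_similarity, k0=3, seed=0, restarts=3)
        np.testing.assert_array_equal(res.labels, fun.labels)
        assert res.model is not None

    def test_from_features_pipeline(self):
        from shrinkclust import gaussian_blobs

        X, truth = gaussian_blobs([(-6, 0), (6, 0)], 20, seed=0)
        model = ShrinkageClustering.from_features(X, standardize=True)
        assert model.kernel_params is not None
        res = model.fit(k0=10, seed=0)
        assert res.k_final >= 1

    def test_summary_mentions_key_quantities(self, toy_similarity):
        res = ShrinkageClustering(toy_similarity).fit(k0=3, seed=1, restarts=3)
        text = res.summary()
        assert "clusters (K)" in text and "objective" in text
        assert str(res.k_final) in text

    def test_plot_path_returns_axis(self, toy_similarity):
        import matplotlib

        matplotlib.use("Agg")
        res = ShrinkageClustering(toy_similarity).fit(k0=3, seed=0)
        ax = res.plot_path()
        assert ax.get_xlabel() == "iteration"
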