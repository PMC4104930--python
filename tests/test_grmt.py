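"""Graph-regularized multi-task SVR: Laplacian, coupling penalty, joint
training, and the unseen-task adaptation."""

import numpy as np
import pytest

from mtqsar.data import MultiTaskDataset
from mtqsar.grmt import (
    adapt_for_unseen_task,
    graph_laplacian,
    grmt_regularizer,
    predict_task,
    train_grmt,
)
from mtqsar.svr import solve_dual

from conftest import grmt_primal_oracle


def random_multitask(rng, T=3, per_task=4, n=4):
    X = rng.random((T * per_task, n))
    y = rng.normal(0, 1, T * per_task)
    tids = np.repeat(np.arange(1, T + 1), per_task)
    return MultiTaskDataset(X, y, tids)


def random_adjacency(rng, T):
    A = rng.random((T, T))
    A = (A + A.T) / 2
    np.fill_diagonal(A, 1.0)
    return A


class TestGraphLaplacian:
    def test_identity_adjacency_gives_zero_laplacian(self):
        lap = graph_laplacian(np.eye(4))
        np.testing.assert_allclose(lap.L, np.zeros((4, 4)))
        np.testing.assert_allclose(lap.M, np.eye(4))

    def test_two_by_two_all_ones(self):
        lap = graph_laplacian(np.ones((2, 2)))
        np.testing.assert_allclose(lap.L, [[1.0, -1.0], [-1.0, 1.0]])

    def test_rejects_asymmetric_and_negative(self):
        with pytest.raises(ValueError):
            graph_laplacian(np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(ValueError):
            graph_laplacian(np.array([[1.0, -0.5], [-0.5, 1.0]]))

    def test_laplacian_is_positive_semidefinite(self, rng):
        for _ in range(10):
            A = random_adjacency(rng, int(rng.integers(2, 7)))
            lap = graph_laplacian(A)
            assert np.linalg.eigvalsh(lap.L).min() >= -1e-10

    def test_diagonal_of_A_is_irrelevant(self, rng):
        """The self-similarity convention cancels in D - A."""
        A = random_adjacency(rng, 4)
        shifted = A + np.diag(rng.random(4))
        np.testing.assert_allclose(
            graph_laplacian(A).L, graph_laplacian(shifted).L, atol=1e-12
        )


class TestRegularizer:
    def test_equal_weights_give_zero(self):
        W = np.tile(np.array([1.0, 2.0]), (3, 1))
        assert grmt_regularizer(W, np.ones((3, 3))) == pytest.approx(0.0)

    def test_orthonormal_pair(self):
        W = np.array([[1.0, 0.0], [0.0, 1.0]])
        A = np.array([[0.0, 1.0], [1.0, 0.0]])
        assert grmt_regularizer(W, A) == pytest.approx(1.0)

    def test_pairwise_and_laplacian_forms_agree(self, rng):
        for _ in range(10):
            T, n = int(rng.integers(2, 6)), int(rng.integers(1, 5))
            W = rng.normal(0, 1, (T, n))
            A = random_adjacency(rng, T)
            L = graph_laplacian(A).L
            quad = 0.5 * float(np.einsum("st,si,ti->", L, W, W))
            assert grmt_regularizer(W, A) == pytest.approx(quad, abs=1e-9)

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(ValueError):
            grmt_regularizer(np.zeros((2, 3)), np.eye(3))


class TestTrainGRMT:
    def test_identity_similarity_equals_independent_svrs(self, rng):
        """A = I decouples tasks into per-task SVRs at shared C."""
        ds = random_multitask(rng, T=3, per_task=5)
        m = train_grmt(ds, np.eye(3), C=1.0, epsilon=0.1, tol=1e-9,
                       max_iter=50000)
        offset = ds.y.mean()
        for t in ds.tasks:
            sub = ds.task_subset(int(t))
            _, w = solve_dual(sub.X, sub.y - offset, 1.0, 0.1, tol=1e-9,
                              max_iter=50000)
            assert np.max(np.abs(w - m.weights[t - 1])) < 1e-5

    def test_identical_tasks_get_identical_weights(self, rng):
        X = rng.random((4, 3))
        y = rng.normal(0, 1, 4)
        ds = MultiTaskDataset(
            np.vstack([X, X, X]), np.tile(y, 3),
            np.repeat([1, 2, 3], 4),
        )
        A = random_adjacency(rng, 3)
        m = train_grmt(ds, A, C=2.0, epsilon=0.1, tol=1e-10, max_iter=50000)
        assert np.max(np.abs(m.weights[0] - m.weights[1])) < 1e-6
        assert np.max(np.abs(m.weights[0] - m.weights[2])) < 1e-6

    def test_matches_joint_primal_oracle(self, rng):
        for _ in range(6):
            T = int(rng.integers(2, 4))
            ds = random_multitask(rng, T=T, per_task=3, n=4)
            A = random_adjacency(rng, T)
            m = train_grmt(ds, A, C=1.0, epsilon=0.1, tol=1e-10,
                           max_iter=50000)
            W_star = grmt_primal_oracle(
                ds.X.toarray(), ds.y - ds.y.mean(), ds.task_ids, A, 1.0, 0.1
            )
            assert np.max(np.abs(m.weights - W_star)) < 1e-5

    def test_objective_not_worse_than_decoupled_solution(self, rng):
        """The joint minimizer beats the independently trained weights on
        the joint objective."""
        from mtqsar.grmt import grmt_primal_objective

        ds = random_multitask(rng, T=3, per_task=5)
        A = random_adjacency(rng, 3)
        m = train_grmt(ds, A, C=1.0, epsilon=0.1, tol=1e-9, max_iter=50000)
        m_ind = train_grmt(ds, np.eye(3), C=1.0, epsilon=0.1, tol=1e-9,
                           max_iter=50000)
        j_joint = grmt_primal_objective(ds, m.weights, A, 1.0, 0.1)
        j_ind = grmt_primal_objective(ds, m_ind.weights, A, 1.0, 0.1)
        assert j_joint <= j_ind + 1e-8

    def test_coupling_scale_interpolates_between_extremes(self, rng):
        """Off-diagonal scale -> 0 recovers independent training; a large
        scale forces all task weights together."""
        ds = random_multitask(rng, T=3, per_task=5)
        A1 = random_adjacency(rng, 3)
        m_ind = train_grmt(ds, np.eye(3), C=1.0, epsilon=0.1, tol=1e-9,
                           max_iter=50000)
        off = A1 - np.diag(np.diag(A1))
        scales = [1e-6, 1e-2, 1.0, 1e3]
        spreads = []
        for s in scales:
            m = train_grmt(ds, np.eye(3) + s * off, C=1.0, epsilon=0.1,
                           tol=1e-10, max_iter=100000)
            spreads.append(max(
                np.max(np.abs(m.weights[a] - m.weights[b]))
                for a in range(3) for b in range(a + 1, 3)
            ))
            if s == 1e-6:
                assert np.max(np.abs(m.weights - m_ind.weights)) < 1e-4
        assert all(a >= b - 1e-9 for a, b in zip(spreads, spreads[1:]))
        # near-uniform weights at huge coupling
        assert spreads[-1] < 1e-2 * spreads[0]

    def test_task_id_out_of_range_rejected(self, rng):
        ds = random_multitask(rng, T=3, per_task=2)
        with pytest.raises(ValueError):
            train_grmt(ds, np.eye(2), C=1.0)

    def test_predict_task_validates_task(self, rng):
        ds = random_multitask(rng, T=2, per_task=3)
        m = train_grmt(ds, np.eye(2), C=1.0)
        with pytest.raises(ValueError):
            predict_task(m, ds.X[0], 3)


class TestUnseenTaskAdaptation:
    def test_single_edge_copies_the_neighbor_weight(self, rng):
        """With one unit edge and no ridge on the held-out task, its weight
        must coincide with the neighbor's at the optimum."""
        A = np.zeros((2, 2))
        A[0, 1] = A[1, 0] = 1.0
        np.fill_diagonal(A, 1.0)
        lap = adapt_for_unseen_task(A, t_out=2)
        X = rng.random((6, 3))
        y = rng.normal(0, 1, 6)
        ds = MultiTaskDataset(X, y, np.ones(6, dtype=int))
        m = train_grmt(ds, A, C=1.0, epsilon=0.1, laplacian=lap, tol=1e-10,
                       max_iter=50000)
        assert np.max(np.abs(m.weights[0] - m.weights[1])) < 1e-8

    def test_isolated_heldout_task_rejected(self):
        A = np.eye(3)
        with pytest.raises(ValueError):
            adapt_for_unseen_task(A, t_out=2)

    def test_three_task_adaptation_matches_modified_primal_oracle(self, rng):
        from conftest import lbfgs

        T, n = 3, 3
        A = random_adjacency(rng, T)
        t_out = 3
        X = rng.random((8, n))
        y = rng.normal(0, 1, 8)
        tids = np.repeat([1, 2], 4)
        ds = MultiTaskDataset(X, y, tids)
        lap = adapt_for_unseen_task(A, t_out)
        m = train_grmt(ds, A, C=1.0, epsilon=0.1, laplacian=lap, tol=1e-10,
                       max_iter=50000)
        yc = y - y.mean()
        L = lap.L

        def P(flat):
            W = flat.reshape(T, n)
            ridge = 0.5 * sum(
                W[t] @ W[t] for t in range(T) if t != t_out - 1
            )
            coupling = 0.5 * np.einsum("st,si,ti->", L, W, W)
            # the Laplacian form already carries the full coupling; the
            # ridge excludes the held-out task
            pred = np.einsum("ij,ij->i", X, W[tids - 1])
            loss = np.maximum(np.abs(pred - yc) - 0.1, 0.0) ** 2
            return ridge + coupling + loss.sum()

        W_star = lbfgs(P, np.zeros(T * n)).reshape(T, n)
        assert np.max(np.abs(m.weights - W_star)) < 1e-5
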