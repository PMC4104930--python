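"""Evaluation harness: error metric, grids, protocols, equivalences and the
paired significance machinery."""

import numpy as np
import pandas as pd
import pytest

from mtqsar.data import MultiTaskDataset
from mtqsar.evaluate import (
    ExperimentProtocol,
    Split,
    leave_one_sequence_out,
    make_grids,
    mse,
    paired_tests,
    random_splits,
    run_protocol,
    simulated_splits,
)
from mtqsar.simulate import SimulationConfig
from mtqsar.taxonomy import star_taxonomy


class TestMSE:
    def test_identical_vectors_give_zero(self):
        assert mse([1.0, 2.0], [1.0, 2.0]) == 0.0

    def test_unit_residuals(self):
        assert mse([0.0, 0.0], [1.0, 1.0]) == 1.0

    def test_matches_independent_recomputation(self, rng):
        a, b = rng.normal(0, 1, 50), rng.normal(0, 1, 50)
        direct = sum((x - y) ** 2 for x, y in zip(a, b)) / 50
        assert mse(a, b) == pytest.approx(direct)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mse([], [])


class TestGrids:
    def test_default_grid(self):
        C, B, eps = make_grids("default")
        assert len(C) == 7
        assert C[0] == pytest.approx(0.03125)
        assert C[-1] == pytest.approx(128.0)
        assert eps == 0.1

    def test_kinome_grmt_grid(self):
        C, _, _ = make_grids("kinome_grmt")
        assert len(C) == 4 and C[-1] == pytest.approx(256.0)

    def test_B_grid_contents(self):
        _, B, _ = make_grids()
        assert len(B) == 7 and 0.0 in B and 1.0 in B

    def test_unknown_setting_rejected(self):
        with pytest.raises(ValueError):
            make_grids("bogus")


class TestProtocolValidation:
    def test_small_test_size_rejected(self):
        with pytest.raises(ValueError):
            ExperimentProtocol(test_size=4)

    def test_fold_counts_validated(self):
        with pytest.raises(ValueError):
            ExperimentProtocol(inner_folds=1)


def small_sim_splits(n_splits=2, **kw):
    cfg = SimulationConfig(N=12, T=3, D=5, beta=3.0, sigma2=1.5, n_test=6,
                           seed=kw.pop("seed", 0))
    return simulated_splits(cfg, n_splits=n_splits, **kw)


class TestRunProtocol:
    def test_identity_similarity_grmt_matches_tsvm_tables(self):
        """With A = I and a one-point C grid the graph method decouples into
        the per-task baseline.  (The two center labels differently — per
        task vs globally — so task label means are equalized first.)"""
        splits = small_sim_splits()
        for s in splits:
            s.similarity = np.eye(3)
            for part in (s.train, s.test):
                for t in part.tasks:
                    mask = part.task_ids == t
                    part.y[mask] -= s.train.y[s.train.task_ids == t].mean()
        tab = run_protocol(["tSVM", "GRMT"], splits, C_grid=[1.0],
                           inner_folds=2, seed=0, tol=1e-8, max_iter=20000)
        wide = tab.pivot_table(index=["task", "split"], columns="algorithm",
                               values="mse")
        np.testing.assert_allclose(wide["tSVM"], wide["GRMT"], rtol=1e-4)

    def test_pooled_baseline_matches_topdown_root(self):
        """A star taxonomy with full pull at every leaf is dominated by the
        root; the root model itself is the pooled baseline."""
        from mtqsar.svr import train_svr
        from mtqsar.tdmt import TDMTConfig, train_topdown

        splits = small_sim_splits(1)
        split = splits[0]
        cfg = TDMTConfig(mode="tax", C_grid=(1.0,), tol=1e-8, max_iter=20000)
        m = train_topdown(split.taxonomy, split.train, cfg)
        ref = train_svr(split.train, 1.0, 0.1, tol=1e-8, max_iter=20000)
        assert np.max(np.abs(m.root.weight - ref.weight)) < 1e-4

    def test_pairing_structure_is_complete(self):
        splits = small_sim_splits()
        tab = run_protocol(["tSVM", "1SVM"], splits, C_grid=[1.0],
                           inner_folds=2, seed=0)
        counts = tab.groupby("algorithm").size()
        assert counts.nunique() == 1  # identical (task, split) coverage

    def test_multitask_beats_independent_on_similar_scarce_data(self):
        """High task similarity and small N: graph-coupled training achieves
        a lower mean test error than independent models."""
        cfg = SimulationConfig(N=15, T=5, D=14, beta=3.0, sigma2=1.5,
                               n_test=25, seed=0)
        splits = simulated_splits(cfg, n_splits=10)
        tab = run_protocol(["tSVM", "GRMT"], splits,
                           C_grid=[0.125, 2.0, 32.0], inner_folds=3, seed=0)
        g = tab.groupby("algorithm").mse.mean()
        assert g["GRMT"] < g["tSVM"]


class TestRandomSplits:
    def test_tasks_below_budget_are_excluded(self, rng, caplog):
        X = rng.random((30, 4))
        y = rng.normal(0, 1, 30)
        tids = np.concatenate([np.ones(25, dtype=int), np.full(5, 2)])
        ds = MultiTaskDataset(X, y, tids)
        proto = ExperimentProtocol(repetitions=2, train_size=10, test_size=5,
                                   seed=0)
        splits = random_splits(ds, proto)
        assert set(np.unique(splits[0].train.task_ids)) == {1}

    def test_train_and_test_never_overlap(self, rng):
        X = rng.random((40, 4))
        y = rng.normal(0, 1, 40)
        ds = MultiTaskDataset(X, y, np.ones(40, dtype=int))
        proto = ExperimentProtocol(repetitions=3, train_size=20, test_size=10,
                                   seed=1)
        for s in random_splits(ds, proto):
            assert not set(s.train.instance_ids) & set(s.test.instance_ids)


class TestLeaveOneSequenceOut:
    def test_budget_redistribution_preserves_total(self):
        cfg = SimulationConfig(N=10, T=3, D=4, beta=3.0, sigma2=1.5,
                               n_test=5, seed=2)
        splits = simulated_splits(cfg, n_splits=1, pool_factor=2)
        from mtqsar.evaluate import _redistribute_budget

        pool = splits[0].pool
        rows = _redistribute_budget(pool, [1, 2, 3], 2, 10)
        assert len(rows) == 30  # 3 tasks x 10 = total budget, kept constant
        assert not np.any(pool.task_ids[rows] == 2)

    def test_star_taxonomy_heldout_equals_pooled_model(self):
        """The held-out leaf's parent is the root, so the top-down method
        predicts with the pooled model."""
        cfg = SimulationConfig(N=10, T=3, D=4, beta=3.0, sigma2=1.5,
                               n_test=5, seed=3)
        splits = simulated_splits(cfg, n_splits=1, pool_factor=2)
        tab = leave_one_sequence_out(["1SVM", "TDMTtax"], splits,
                                     C_grid=[1.0], inner_folds=2, seed=0,
                                     tol=1e-8, max_iter=20000,
                                     train_size=10)
        wide = tab.pivot_table(index=["task", "split"], columns="algorithm",
                               values="mse")
        np.testing.assert_allclose(wide["1SVM"], wide["TDMTtax"], rtol=1e-5)

    def test_zero_similarity_heldout_task_skips_graph_method(self, caplog):
        cfg = SimulationConfig(N=10, T=3, D=4, beta=3.0, sigma2=1.5,
                               n_test=5, seed=4)
        splits = simulated_splits(cfg, n_splits=1, pool_factor=2)
        A = np.eye(3)
        splits[0].similarity = A
        import logging

        with caplog.at_level(logging.INFO, logger="mtqsar.evaluate"):
            tab = leave_one_sequence_out(["GRMT"], splits, C_grid=[1.0],
                                         inner_folds=2, seed=0, train_size=10)
        assert tab.empty
        assert any("skipped" in r.message for r in caplog.records)


class TestPairedTests:
    def make_table(self, a_vals, b_vals, task=1):
        rows = []
        for j, (a, b) in enumerate(zip(a_vals, b_vals)):
            rows.append({"algorithm": "A", "task": task, "split": j, "mse": a})
            rows.append({"algorithm": "B", "task": task, "split": j, "mse": b})
        return pd.DataFrame(rows)

    def test_identical_performance_is_nochange_and_flagged(self):
        tab = self.make_table([1.0] * 8, [1.0] * 8)
        res = paired_tests(tab, "A", "B")
        assert res.label.iloc[0] == "NoChange"
        assert bool(res.degenerate.iloc[0])
        assert res.p_raw.iloc[0] == 1.0

    def test_holm_adjustment_of_two_pvalues(self):
        """Holm on raw p {0.01, 0.04} with m=2 gives {0.02, 0.04}."""
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([0.01, 0.04], method="holm")
        np.testing.assert_allclose(p_adj, [0.02, 0.04])

    def test_bh_adjustment_of_two_pvalues(self):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, _, _ = multipletests([0.01, 0.04], method="fdr_bh")
        np.testing.assert_allclose(p_adj, [0.02, 0.04])

    def test_clear_difference_is_labelled_better(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1.0, 0.01, 12)
        b = a + 1.0  # B much worse
        res = paired_tests(self.make_table(a, b), "A", "B")
        assert res.label.iloc[0] == "Better"

    def test_unpaired_input_rejected(self):
        tab = self.make_table([1.0] * 4, [2.0] * 4)
        tab = tab.drop(index=[0])  # break pairing
        with pytest.raises(ValueError):
            paired_tests(tab, "A", "B")

    def test_null_rejection_rate_is_calibrated(self):
        """Two identical algorithms on resampled noise: the Wilcoxon test at
        alpha=0.05 rejects about 5% of the time over 1000 tables."""
        rng = np.random.default_rng(12)
        rejections = 0
        n_tables = 1000
        for _ in range(n_tables):
            base = rng.normal(1.0, 0.2, 10)
            a = base + rng.normal(0, 0.05, 10)
            b = base + rng.normal(0, 0.05, 10)
            res = paired_tests(self.make_table(a, b), "A", "B")
            rejections += int(res.significant.iloc[0])
        rate = rejections / n_tables
        assert 0.03 <= rate <= 0.07
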