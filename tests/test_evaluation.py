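import numpy as np
import pytest
import scipy.sparse as sp
from sklearn.preprocessing import normalize

from multirank.evaluation import (
    RANK_C_GRID,
    SVC_C_GRID,
    ExperimentConfig,
    add_decoys,
    auc,
    cutoff_sweep,
    grid_search_C,
    label_test_sets,
    profile_balanced_sample,
    run_experiment,
)
from multirank.profile_encoding import build_scheme
from multirank.ranksvm import rank_error
from multirank.synthetic import SyntheticSpec, make_benchmark

SMALL_DESIGN = {
    (1, 0, 0): 16, (0, 1, 0): 16, (0, 0, 1): 16,
    (1, 1, 0): 10, (1, 0, 1): 10, (0, 1, 1): 10,
    (1, 1, 1): 8, (0, 0, 0): 60,
}


@pytest.fixture(scope="module")
def small_bench():
    bench = make_benchmark(SyntheticSpec(overlap_design=SMALL_DESIGN, seed=21,
                                         activation_prob=0.9,
                                         background_noise=0.002))
    return normalize(bench.X), bench.profiles


class TestSampling:
    def _groups(self, sizes):
        profiles = [(1, 0, 0), (0, 1, 0), (0, 0, 1)]
        out, start = {}, 0
        for p, size in zip(profiles, sizes):
            out[p] = np.arange(start, start + size)
            start += size
        return out

    def test_half_of_smallest_subset(self):
        groups = self._groups([10, 40, 60])
        train, rest = profile_balanced_sample(groups, "single",
                                              np.random.default_rng(0))
        assert train.size == 15  # n=5 from each of the three subsets
        for p, ids in groups.items():
            assert np.intersect1d(train, ids).size == 5

    def test_floor_on_odd_sizes(self):
        groups = self._groups([8, 8, 8])
        train, _ = profile_balanced_sample(groups, "single",
                                           np.random.default_rng(0))
        assert train.size == 12  # n = 4 per subset

    def test_seeded_reproducible_but_seed_dependent(self):
        groups = self._groups([10, 40, 60])
        t1, _ = profile_balanced_sample(groups, "single", np.random.default_rng(1))
        t2, _ = profile_balanced_sample(groups, "single", np.random.default_rng(1))
        t3, _ = profile_balanced_sample(groups, "single", np.random.default_rng(2))
        assert (t1 == t2).all()
        assert not np.array_equal(t1, t3)

    def test_tiny_subset_fatal(self):
        groups = self._groups([1, 40, 60])
        with pytest.raises(ValueError, match="fewer than 2"):
            profile_balanced_sample(groups, "single", np.random.default_rng(0))

    def test_train_and_rest_partition_category(self):
        groups = self._groups([10, 40, 60])
        train, rest = profile_balanced_sample(groups, "single",
                                              np.random.default_rng(3))
        union = np.sort(np.concatenate([train, rest]))
        assert (union == np.arange(110)).all()


class TestDecoys:
    def test_exact_count(self):
        out = add_decoys(np.arange(5), np.arange(100, 2000), k=1000,
                         rng=np.random.default_rng(0))
        assert out.size == 1005
        assert np.unique(out[5:]).size == 1000

    def test_saturation_warns_and_uses_all(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            out = add_decoys(np.arange(5), np.arange(100, 160), k=1000,
                             rng=np.random.default_rng(0))
        assert out.size == 65
        assert "smaller" in caplog.text

    def test_disjoint_from_actives(self):
        pool = np.arange(50, 500)
        out = add_decoys(np.arange(10), pool, k=100, rng=np.random.default_rng(1))
        assert not np.intersect1d(out[:10], out[10:]).size


class TestGrids:
    def test_default_grids_match_protocol(self):
        assert RANK_C_GRID == (1e-6, 1e-5, 1e-4, 1e-3, 1e-2)
        assert SVC_C_GRID == (0.1, 1.0, 10.0, 100.0, 1000.0)

    def test_single_value_grid_short_circuits(self, small_bench):
        X, profiles = small_bench
        scheme = build_scheme(3, [0])
        c = grid_search_C("mtrank", X, profiles, scheme, [1e-3],
                          rng=np.random.default_rng(0))
        assert c == 1e-3

    def test_returns_grid_member_deterministically(self, small_bench):
        X, profiles = small_bench
        scheme = build_scheme(3, [0])
        cfg = ExperimentConfig(method="mtrank", scheme=scheme)
        c1 = grid_search_C("mtrank", X, profiles, scheme, RANK_C_GRID,
                           rng=np.random.default_rng(7), cfg=cfg)
        c2 = grid_search_C("mtrank", X, profiles, scheme, RANK_C_GRID,
                           rng=np.random.default_rng(7), cfg=cfg)
        assert c1 == c2
        assert c1 in RANK_C_GRID


class TestLabeling:
    def test_dual_labelings_of_test_set(self, table1_scheme, table2_scheme):
        binary, graded = label_test_sets(
            np.array([(1, 1, 0), (0, 0, 0)]), table1_scheme)
        assert binary.tolist() == [1, 0]
        assert graded.tolist() == [2, 0]
        binary2, graded2 = label_test_sets(np.array([(1, 1, 1)]), table2_scheme)
        assert binary2.tolist() == [1]
        assert graded2.tolist() == [1]


class TestAuc:
    def test_perfect_separation(self):
        assert auc([3.0, 2.0, 0.1, 0.0], [1, 1, 0, 0]) == 1.0

    def test_identity_with_rank_error(self, rng):
        for _ in range(20):
            labels = rng.integers(0, 2, 40)
            labels[:2] = [0, 1]
            preds = np.round(rng.normal(size=40), 1)
            assert auc(preds, labels) + rank_error(preds, labels) == pytest.approx(
                1.0, abs=1e-12)

    def test_random_interleaving_near_half(self, rng):
        labels = rng.integers(0, 2, 4000)
        labels[:2] = [0, 1]
        preds = rng.normal(size=4000)
        assert auc(preds, labels) == pytest.approx(0.5, abs=0.05)

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="single class"):
            auc([1.0, 2.0], [1, 1])


@pytest.fixture(scope="module")
def tiny_cfg():
    return dict(repetitions=3, decoys_per_train=30, seed=42,
                C_grid=(1e-4, 1e-3), cv_tol=1e-2, cv_max_iter=60)


class TestRunExperiment:
    def test_row_per_repetition_and_metric_range(self, small_bench, tiny_cfg):
        X, profiles = small_bench
        cfg = ExperimentConfig(method="mtrank", scheme=build_scheme(3, [0]),
                               **tiny_cfg)
        result = run_experiment(cfg, X, profiles)
        assert len(result.table) == 3
        assert result.table.rank_error_binary.between(0, 1).all()
        assert result.table.kpartite_error_graded.between(0, 1).all()

    def test_no_train_test_leak(self, small_bench, tiny_cfg):
        X, profiles = small_bench
        cfg = ExperimentConfig(method="mtrank", scheme=build_scheme(3, [0]),
                               **tiny_cfg)
        result = run_experiment(cfg, X, profiles)
        assert (result.table.n_train + result.table.n_test == len(profiles)).all()

    def test_deterministic_given_seed(self, small_bench, tiny_cfg):
        X, profiles = small_bench
        cfg = ExperimentConfig(method="svm_lc", scheme=build_scheme(3, [0, 1]),
                               C_grid=(1.0,), repetitions=2,
                               decoys_per_train=30, seed=9)
        r1 = run_experiment(cfg, X, profiles)
        r2 = run_experiment(cfg, X, profiles)
        assert r1.table.equals(r2.table)

    def test_summary_aggregates_per_method(self, small_bench, tiny_cfg):
        X, profiles = small_bench
        cfg = ExperimentConfig(method="mcsvm", scheme=build_scheme(3, [0]),
                               C_grid=(1.0,), repetitions=2,
                               decoys_per_train=30, seed=1)
        summary = run_experiment(cfg, X, profiles).summary()
        assert "kpartite_error_graded_mean" in summary.columns
        assert summary.index.tolist() == ["mcsvm"]

    def test_srank_runs_with_three_levels(self, small_bench, tiny_cfg):
        X, profiles = small_bench
        cfg = ExperimentConfig(method="srank", scheme=build_scheme(3, [0]),
                               **tiny_cfg)
        result = run_experiment(cfg, X, profiles)
        assert len(result.table) == 3


class TestCutoffSweep:
    def _pki_data(self, rng, n=160):
        # three targets; pK_i values spread around the cutoffs
        values = rng.normal(5.9, 0.9, size=(n, 3))
        X = sp.random(n, 64, density=0.2, random_state=np.random.RandomState(0),
                      format="csr")
        # tie features to the first target's activity so learning is possible
        X = X.tolil()
        for i in range(n):
            X[i, 0] = values[i, 0]
        return sp.csr_matrix(X), values

    def test_three_cutoffs_three_result_sets(self, rng):
        X, values = self._pki_data(rng)
        scheme = build_scheme(3, [0], secondary_priority=[1, 2],
                              nonselective_as_decoy=True)
        cfg = ExperimentConfig(method="svc", scheme=scheme, repetitions=2,
                               C_grid=(1.0,), seed=2)
        results = cutoff_sweep(values, (5.6, 6.1, 6.6), cfg, X)
        assert sorted(results) == [5.6, 6.1, 6.6]
        for res in results.values():
            assert len(res.table) == 2

    def test_extreme_cutoff_fatal(self, rng):
        X, values = self._pki_data(rng)
        scheme = build_scheme(3, [0])
        cfg = ExperimentConfig(method="svc", scheme=scheme, repetitions=1)
        with pytest.raises(ValueError, match="no active"):
            cutoff_sweep(values, (99.0,), cfg, X)

    def test_stratified_split_balances_labels(self, rng):
        from multirank.evaluation import _one_repetition
        from multirank.profile_encoding import encode_profile

        X, values = self._pki_data(rng)
        profiles = (values >= 6.1).astype(int)
        scheme = build_scheme(3, [0])
        cfg = ExperimentConfig(method="svc", scheme=scheme, repetitions=1,
                               C_grid=(1.0,), protocol="stratified_split",
                               seed=0)
        row = _one_repetition(cfg, X, profiles, 0)
        # half of each score level (floored) goes to training
        graded = np.array([encode_profile(scheme, p) for p in profiles])
        expected = sum(int((graded == v).sum()) // 2 for v in np.unique(graded))
        assert row["n_train"] == expected
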