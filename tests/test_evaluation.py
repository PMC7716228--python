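"""Clustering, folds, cross-validation, accuracy, and response to selection."""

import itertools
import math

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from mtgp import evaluation, genoqc
from mtgp.containers import MarkerMatrix
from mtgp.simdata import SimConfig, simulate_marker_matrix

from conftest import as_blue_table


class TestClusterPanel:
    def test_two_identical_blocks_perfectly_separated(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, size=60)
        b = rng.integers(0, 3, size=60)
        vals = np.vstack([np.tile(a, (10, 1)), np.tile(b, (10, 1))]).astype(np.int8)
        vals[:, 0] = np.arange(20) % 3  # break exact collinearity
        m = MarkerMatrix(vals, [f"L{i}" for i in range(20)], [f"M{j}" for j in range(60)])
        model = evaluation.cluster_panel(m, k=2, seed=0)
        groups = [set(np.where(model.assignments == c)[0]) for c in (0, 1)]
        assert {frozenset(g) for g in groups} == {
            frozenset(range(10)), frozenset(range(10, 20))
        }
        assert model.posteriors.max(axis=1).min() > 0.9

    def test_recovers_planted_subpopulations(self):
        cfg = SimConfig(n_lines=237, n_checks=0, n_markers=900, n_subpops=10,
                        fst=0.4, het_rate=0.0, missing_rate=0.0, seed=3)
        markers, labels = simulate_marker_matrix(cfg)
        markers, _ = genoqc.filter_markers(markers)
        model = evaluation.cluster_panel(markers, k=10, seed=1)
        assert adjusted_rand_score(labels, model.assignments) > 0.9

    def test_posteriors_sum_to_one_and_k_groups_nonempty(self, structured_panel):
        model = evaluation.cluster_panel(structured_panel["markers"], k=10, seed=0)
        np.testing.assert_allclose(model.posteriors.sum(axis=1), 1.0, atol=1e-8)
        assert (model.sizes() > 0).all()

    def test_k_larger_than_panel_rejected(self, structured_panel):
        with pytest.raises(ValueError):
            evaluation.cluster_panel(structured_panel["markers"], k=10_000)


class TestMakeFolds:
    def test_237_lines_5_random_folds_sizes(self):
        lines = [f"L{i}" for i in range(237)]
        fa = evaluation.make_folds(lines, f=5, scheme="random", seed=0)
        sizes = sorted(np.bincount(fa.folds, minlength=5), reverse=True)
        assert sizes == [48, 48, 47, 47, 47]

    def test_14_line_cluster_round_robin_contribution(self):
        lines = [f"L{i}" for i in range(70)]
        clusters = np.repeat(np.arange(5), 14)  # five 14-line clusters
        fa = evaluation.make_folds(lines, f=5, scheme="stratified",
                                   clusters=clusters, seed=1)
        for c in range(5):
            counts = np.bincount(fa.folds[clusters == c], minlength=5)
            assert sorted(counts, reverse=True) == [3, 3, 3, 3, 2]

    @pytest.mark.parametrize("scheme", ["random", "stratified"])
    def test_partition_invariants_across_100_seeds(self, scheme):
        rng = np.random.default_rng(0)
        n, f = 123, 5
        lines = [f"L{i}" for i in range(n)]
        clusters = rng.integers(0, 7, size=n)
        for seed in range(100):
            fa = evaluation.make_folds(lines, f=f, scheme=scheme,
                                       clusters=clusters, seed=seed)
            sizes = np.bincount(fa.folds, minlength=f)
            assert sizes.sum() == n  # disjoint cover
            assert sizes.max() - sizes.min() <= 1
            if scheme == "stratified":
                for c in np.unique(clusters):
                    cc = np.bincount(fa.folds[clusters == c], minlength=f)
                    assert cc.max() - cc.min() <= 1

    def test_round_trip_through_frame(self):
        lines = [f"L{i}" for i in range(20)]
        fa = evaluation.make_folds(lines, f=4, seed=3)
        back = evaluation.FoldAssignment.from_frame(fa.to_frame())
        np.testing.assert_array_equal(back.folds, fa.folds)

    def test_errors(self):
        with pytest.raises(ValueError):
            evaluation.make_folds(["a", "b"], f=5)
        with pytest.raises(ValueError):
            evaluation.make_folds(["a"] * 10, f=2, scheme="stratified")


class TestCrossValidate:
    @staticmethod
    def _setup(n=60, seed=0):
        rng = np.random.default_rng(seed)
        y = rng.standard_normal((n, 2, 2))
        lines = [f"L{i:03d}" for i in range(n)]
        bt = as_blue_table(y, lines)
        folds = evaluation.make_folds(lines, f=3, seed=seed)
        return bt, folds

    def test_oracle_model_scores_one(self, structured_panel):
        bt, folds = self._setup()
        full = bt.values.copy()

        def oracle(masked, grm):
            return full

        cv = evaluation.cross_validate(oracle, bt, structured_panel["grm"], folds)
        np.testing.assert_allclose(cv.rp, 1.0)

    def test_mean_only_model_has_no_skill(self, structured_panel):
        rs = []
        for seed in range(5):
            bt, folds = self._setup(seed=seed)

            def mean_model(masked, grm):
                mu = np.nanmean(masked.values, axis=0)
                noise = np.random.default_rng(987).normal(0, 1e-6, masked.values.shape)
                return np.broadcast_to(mu, masked.values.shape) + noise

            cv = evaluation.cross_validate(mean_model, bt, structured_panel["grm"], folds)
            rs.append(np.nanmean(cv.rp))
        assert abs(np.mean(rs)) < 0.15

    def test_per_env_masking_mode_runs(self, structured_panel):
        bt, folds = self._setup()
        calls = []

        def spy(masked, grm):
            calls.append(np.isnan(masked.values).sum())
            return bt.values

        cv = evaluation.cross_validate(spy, bt, structured_panel["grm"], folds,
                                       mask_all_envs=False)
        assert len(calls) == folds.n_folds * 2  # one fit per env per fold
        np.testing.assert_allclose(cv.rp, 1.0)


class TestAccuracy:
    def test_zero_mean_rp_gives_zero_accuracy(self):
        acc, _ = evaluation.prediction_accuracy([0.1, -0.1, 0.05, -0.05], h2=0.3)
        assert acc == pytest.approx(0.0)

    def test_sqrt_h2_scaling(self):
        acc, _ = evaluation.prediction_accuracy([0.4] * 5, h2=0.64)
        assert acc == pytest.approx(0.5)

    def test_identical_folds_have_zero_se(self):
        _, se = evaluation.prediction_accuracy([0.37] * 5, h2=0.5)
        assert se == 0.0

    def test_se_formula(self):
        rp = [0.2, 0.3, 0.4, 0.5, 0.6]
        acc, se = evaluation.prediction_accuracy(rp, h2=0.25)
        assert acc == pytest.approx(np.mean(rp) / 0.5)
        assert se == pytest.approx(np.std(rp, ddof=1) / (math.sqrt(5) * 0.5))

    def test_h2_zero_rejected(self):
        with pytest.raises(ValueError):
            evaluation.prediction_accuracy([0.1, 0.2], h2=0.0)


class TestResponseToSelection:
    def test_toy_case_exact(self):
        pheno = np.arange(1.0, 11.0)
        sel = evaluation.response_to_selection(pheno, pheno, h2=0.5, intensity=0.10)
        assert sel.selected == ["L0009"]
        assert sel.differential == pytest.approx(4.5)
        assert sel.response == pytest.approx(2.25)

    def test_shift_invariance_of_gebv(self):
        rng = np.random.default_rng(0)
        gebv = rng.standard_normal(30)
        pheno = rng.standard_normal(30)
        s1 = evaluation.response_to_selection(gebv, pheno, h2=0.4)
        s2 = evaluation.response_to_selection(gebv + 100.0, pheno, h2=0.4)
        assert s1.response == pytest.approx(s2.response)
        assert s1.selected == s2.selected

    def test_random_gebv_has_null_expected_response(self):
        rng = np.random.default_rng(1)
        pheno = rng.standard_normal(50)
        rs = []
        for _ in range(1000):
            gebv = rng.permutation(pheno)
            rs.append(evaluation.response_to_selection(gebv, pheno, h2=1.0).response)
        se = np.std(rs, ddof=1) / math.sqrt(len(rs))
        assert abs(np.mean(rs)) < 2 * se + 0.02

    def test_truth_ranking_maximizes_differential_bruteforce(self):
        rng = np.random.default_rng(2)
        pheno = rng.standard_normal(10)
        best = evaluation.response_to_selection(pheno, pheno, h2=1.0, intensity=0.10)
        n_sel = 1
        all_s = [
            pheno[list(sub)].mean() - pheno.mean()
            for sub in itertools.combinations(range(10), n_sel)
        ]
        assert best.differential == pytest.approx(max(all_s))

    def test_ties_broken_by_line_id(self):
        gebv = np.array([1.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0])
        ids = [f"L{i}" for i in range(10)]
        sel = evaluation.response_to_selection(gebv, gebv, h2=1.0, intensity=0.10,
                                               line_ids=ids)
        assert sel.selected == ["L0"]

    def test_rts_se_across_folds(self):
        r = np.array([0.1, 0.2, 0.3, 0.4, 0.5])
        assert evaluation.rts_standard_error(r) == pytest.approx(
            np.std(r, ddof=1) / math.sqrt(5)
        )
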