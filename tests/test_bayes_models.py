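"""Gibbs-sampler contracts: prediction, reduction, recovery, stacking."""

import numpy as np
import pytest

from mtgp import bayes_models as bm
from mtgp.containers import BlueTable, GenomicRelationship

from conftest import as_blue_table, planted_gblup_data


def chol_g(grm):
    return np.linalg.cholesky(grm.matrix + 1e-8 * np.eye(grm.n_lines))


class TestMcmcConfig:
    def test_invalid_settings_rejected(self):
        with pytest.raises(ValueError):
            bm.McmcConfig(iterations=100, burn_in=100)
        with pytest.raises(ValueError):
            bm.McmcConfig(iterations=100, burn_in=10, thin=0)


class TestMgblup:
    def test_noise_free_masked_cells_recover_genetic_values(self, structured_panel):
        grm = structured_panel["grm"]
        rng = np.random.default_rng(3)
        g = chol_g(grm) @ rng.standard_normal(grm.n_lines)
        y = np.tile(g[:, None], (1, 2))
        masked_idx = rng.choice(grm.n_lines, 50, replace=False)
        ym = y.copy()
        ym[masked_idx, 1] = np.nan
        bt = as_blue_table(ym, grm.line_ids)
        fit = bm.fit_mgblup(bt, grm, bm.McmcConfig(1000, 400, 1, 5), trait="T1")
        r = np.corrcoef(fit.fitted[masked_idx, 1], g[masked_idx])[0, 1]
        assert r > 0.95

    def test_cv_predictive_correlation_exceeds_030(self, structured_panel):
        """5-fold CV on h2=0.5 data: whole lines masked, predicted from kin."""
        grm = structured_panel["grm"]
        g, y = planted_gblup_data(grm, h2=0.5, seed=3)
        rs = []
        for f in range(5):
            vi = np.arange(grm.n_lines)[f::5]
            ym = y.copy()
            ym[vi] = np.nan
            bt = as_blue_table(ym, grm.line_ids)
            fit = bm.fit_mgblup(bt, grm, bm.McmcConfig(800, 300, 1, f), trait="T1")
            rs.append(np.corrcoef(fit.fitted[vi, 0], y[vi, 0])[0, 1])
        assert np.mean(rs) > 0.3

    def test_identity_grm_predicts_environment_means(self):
        """No-information case: masked lines shrink to the environment mean."""
        n = 100
        rng = np.random.default_rng(2)
        lines = [f"L{i}" for i in range(n)]
        gi = GenomicRelationship(np.eye(n), lines, 1)
        y = np.column_stack([rng.normal(5.0, 1.0, n), rng.normal(8.0, 1.0, n)])
        masked_idx = np.arange(0, n, 5)
        ym = y.copy()
        ym[masked_idx, :] = np.nan
        bt = as_blue_table(ym, lines)
        fit = bm.fit_mgblup(bt, gi, bm.McmcConfig(4000, 1000, 1, 4),
                            trait="T1", include_ge=False)
        env_means = np.nanmean(ym, axis=0)
        dev = np.abs(fit.fitted[masked_idx] - env_means)
        assert dev.max() < 0.35  # posterior-mean shrinkage to the mean, MC error

    def test_seed_reproducibility(self, structured_panel):
        grm = structured_panel["grm"]
        _, y = planted_gblup_data(grm, h2=0.5, seed=1)
        bt = as_blue_table(y, grm.line_ids)
        f1 = bm.fit_mgblup(bt, grm, bm.McmcConfig(300, 100, 1, 42), trait="T1")
        f2 = bm.fit_mgblup(bt, grm, bm.McmcConfig(300, 100, 1, 42), trait="T1")
        np.testing.assert_array_equal(f1.fitted, f2.fitted)

    def test_chains_with_different_seeds_agree(self, structured_panel):
        grm = structured_panel["grm"]
        _, y = planted_gblup_data(grm, h2=0.5, seed=1)
        bt = as_blue_table(y, grm.line_ids)
        fits = [
            bm.fit_mgblup(bt, grm, bm.McmcConfig(1200, 400, 1, s), trait="T1")
            for s in (0, 1)
        ]
        r = np.corrcoef(fits[0].fitted.ravel(), fits[1].fitted.ravel())[0, 1]
        assert r > 0.99


class TestBmtme:
    def test_reduces_to_gblup_single_trait_single_env(self, structured_panel):
        grm = structured_panel["grm"]
        rng = np.random.default_rng(3)
        g = chol_g(grm) @ rng.standard_normal(grm.n_lines)
        y = g + rng.standard_normal(grm.n_lines)
        ym = y.copy()
        ym[::4] = np.nan
        bt = as_blue_table(ym[:, None], grm.line_ids)
        mc = bm.McmcConfig(1500, 500, 1, 9)
        f_gblup = bm.fit_mgblup(bt, grm, mc, trait="T1")
        f_bmtme = bm.fit_bmtme(bt, grm, mc)
        r = np.corrcoef(f_gblup.fitted[:, 0], f_bmtme.fitted[:, 0, 0])[0, 1]
        assert r > 0.99

    def test_recovers_planted_trait_genetic_correlation(self, structured_panel):
        """Matrix-variate generation with rG = 0.6; posterior within 0.15."""
        grm = structured_panel["grm"]
        n = grm.n_lines
        rng = np.random.default_rng(7)
        st = np.array([[1.0, 0.6], [0.6, 1.0]])
        se = np.array([[1.0, 0.3], [0.3, 1.0]])
        cg, cst, cse = chol_g(grm), np.linalg.cholesky(st), np.linalg.cholesky(se)
        b1 = cg @ rng.standard_normal((n, 2)) @ cst.T
        z = rng.standard_normal((2, n, 2))
        b2 = np.einsum("ie,ejl->ijl", cse, np.einsum("jk,ekl->ejl", cg, z)) @ cst.T
        u = b1[None] + b2
        y = np.transpose(u + rng.standard_normal(u.shape) * np.sqrt(2.0), (1, 0, 2))
        bt = as_blue_table(y, grm.line_ids)
        ps = bm.fit_bmtme(bt, grm, bm.McmcConfig(2000, 1000, 1, 13))
        assert ps.rg_traits[0, 1] == pytest.approx(0.6, abs=0.15)

    def test_masked_values_never_influence_the_fit(self, structured_panel):
        """Permuting masked entries must leave predictions unchanged."""
        grm = structured_panel["grm"]
        _, y = planted_gblup_data(grm, n_traits=2, h2=0.5, seed=5)
        y3 = np.stack([y, y + 0.1], axis=1)  # (n, 2 envs, 2 traits)
        mask_lines = np.arange(0, grm.n_lines, 3)
        a = y3.copy()
        a[mask_lines] = np.nan
        b = y3.copy()
        b[mask_lines] = 999.0  # garbage behind the mask
        b[mask_lines] = np.nan
        bt_a = as_blue_table(a, grm.line_ids)
        bt_b = as_blue_table(b, grm.line_ids)
        mc = bm.McmcConfig(200, 100, 1, 3)
        fa = bm.fit_bmtme(bt_a, grm, mc)
        fb = bm.fit_bmtme(bt_b, grm, mc)
        np.testing.assert_array_equal(fa.fitted, fb.fitted)

    def test_no_signal_limit_shrinks_to_cell_means(self):
        """Identity GRM + pure noise: predictions near env x trait means."""
        n = 80
        rng = np.random.default_rng(11)
        lines = [f"L{i}" for i in range(n)]
        gi = GenomicRelationship(np.eye(n), lines, 1)
        y = rng.standard_normal((n, 2, 2)) + np.array([[1.0, 3.0], [5.0, 7.0]])
        bt = as_blue_table(y, lines)
        ps = bm.fit_bmtme(bt, gi, bm.McmcConfig(600, 200, 1, 1))
        spread = ps.fitted.std(axis=0).max()
        assert spread < 0.45 * y.std()


class TestGeneticCorrelations:
    def test_closed_forms(self):
        rg, _ = bm.genetic_correlations(np.array([[1.0, 0.5], [0.5, 1.0]]))
        assert rg[0, 1] == pytest.approx(0.5)
        rg, _ = bm.genetic_correlations(np.diag([2.0, 3.0]))
        assert rg[0, 1] == pytest.approx(0.0)
        assert np.allclose(np.diag(rg), 1.0)

    def test_full_matrix_recovery_from_simulation(self):
        """4x4 target correlation matrix recovered elementwise within 0.15.

        A 300-line, moderately structured panel keeps the effective sample
        large enough that both the realized correlations and the posterior
        land within the tolerance of the generating matrix.
        """
        from mtgp import genoqc
        from mtgp.simdata import SimConfig, simulate_marker_matrix

        cfg = SimConfig(n_lines=300, n_checks=0, n_markers=1300, n_subpops=10,
                        fst=0.15, het_rate=0.0, missing_rate=0.0, seed=19)
        mk, _ = simulate_marker_matrix(cfg)
        mk, _ = genoqc.filter_markers(mk)
        grm = genoqc.build_grm(mk)
        n, n_env = grm.n_lines, 3
        rng = np.random.default_rng(23)
        target = np.array([
            [1.0, 0.67, 0.17, 0.18],
            [0.67, 1.0, 0.17, 0.10],
            [0.17, 0.17, 1.0, -0.32],
            [0.18, 0.10, -0.32, 1.0],
        ])
        cg, ct = chol_g(grm), np.linalg.cholesky(target)
        b1 = cg @ rng.standard_normal((n, 4)) @ ct.T
        z = rng.standard_normal((n_env, n, 4))
        b2 = np.einsum("jk,ekl->ejl", cg, z) @ ct.T
        u = b1[None] + b2
        y = np.transpose(u + rng.standard_normal(u.shape), (1, 0, 2))
        bt = as_blue_table(y, grm.line_ids)
        ps = bm.fit_bmtme(bt, grm, bm.McmcConfig(2500, 1000, 1, 29))
        np.testing.assert_allclose(ps.rg_traits, target, atol=0.15)


class TestBmors:
    def test_scaled_predictions_standardized_on_training_cells(self, structured_panel):
        grm = structured_panel["grm"]
        _, y = planted_gblup_data(grm, n_traits=3, h2=0.6, seed=5)
        y3 = np.stack([y, y * 1.1], axis=1)
        bt = as_blue_table(y3, grm.line_ids)
        fit = bm.fit_bmors(bt, grm, bm.McmcConfig(400, 150, 1, 3), target_trait="T1")
        train = ~fit.mask
        for l in range(3):
            z = (fit.stage1_fitted[:, :, l] - fit.scale_mu[l]) / fit.scale_sd[l]
            assert z[train].mean() == pytest.approx(0.0, abs=1e-9)
            assert z[train].std(ddof=0) == pytest.approx(1.0, abs=1e-9)

    def test_noise_target_gets_null_coefficients(self, structured_panel):
        grm = structured_panel["grm"]
        rng = np.random.default_rng(31)
        _, y = planted_gblup_data(grm, n_traits=2, h2=0.6, seed=6)
        noise = rng.standard_normal(grm.n_lines)
        y3 = np.concatenate([noise[:, None], y], axis=1)[:, None, :]  # traits: noise, T, T
        bt = as_blue_table(y3, grm.line_ids, trait_ids=["N", "A", "B"])
        fit = bm.fit_bmors(bt, grm, bm.McmcConfig(600, 200, 1, 7), target_trait="N")
        # The target's own stage-1 prediction legitimately tracks its
        # training residuals; the traits truly independent of the target
        # ("A", "B") must receive null coefficients.
        for coef, sd in zip(fit.beta_mean[2:], fit.beta_sd[2:]):
            assert abs(coef) < 2.5 * sd + 0.05

    def test_planted_signal_dominates(self, structured_panel):
        """Target equals trait 1's genetic value: beta_1 dwarfs the rest."""
        grm = structured_panel["grm"]
        g, _ = planted_gblup_data(grm, n_traits=3, h2=0.9, seed=8)
        y3 = np.stack([g[:, [0]].repeat(3, axis=1), g], axis=1)
        y3 = np.transpose(y3, (0, 1, 2))
        # traits: target == g1 (noise-free), plus g1, g2, g3 as predictors
        vals = np.concatenate([g[:, [0]], g], axis=1)[:, None, :]
        bt = as_blue_table(vals, grm.line_ids, trait_ids=["tgt", "g1", "g2", "g3"])
        fit = bm.fit_bmors(bt, grm, bm.McmcConfig(600, 200, 1, 9), target_trait="tgt")
        betas = np.abs(fit.beta_mean[1:])  # skip intercept
        # predictors tgt and g1 share the signal; g2/g3 must be negligible
        assert betas[0] + betas[1] > 3 * max(betas[2], betas[3])


class TestLeaveOneEnvOut:
    def test_high_env_correlation_beats_zero_correlation(self, structured_panel):
        grm = structured_panel["grm"]
        n = grm.n_lines
        rng = np.random.default_rng(41)
        cg = chol_g(grm)

        def run(rho, seed):
            cov = np.array([[1.0, rho], [rho, 1.0]])
            u = cg @ rng.standard_normal((n, 2)) @ np.linalg.cholesky(cov).T
            y = u + 0.7 * rng.standard_normal((n, 2))
            bt = as_blue_table(y[:, :, None], grm.line_ids)
            preds = bm.leave_one_env_out_bmors(bt, grm, bm.McmcConfig(500, 200, 1, seed))
            return np.mean([
                np.corrcoef(preds[e][:, 0], y[:, i])[0, 1]
                for i, e in enumerate(bt.env_ids)
            ])

        assert run(0.9, 1) > run(0.0, 2)

    def test_single_environment_rejected(self, structured_panel):
        grm = structured_panel["grm"]
        _, y = planted_gblup_data(grm, h2=0.5, seed=1)
        bt = as_blue_table(y, grm.line_ids)
        with pytest.raises(ValueError, match="at least 2"):
            bm.leave_one_env_out_bmors(bt, grm, bm.McmcConfig(100, 50, 1, 0))
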