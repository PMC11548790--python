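import numpy as np
import pandas as pd
import pytest

from sparsemet.designs import cv_partitions
from sparsemet.engine import (
    EnvCovariance,
    GBLUPFit,
    MCMCConfig,
    PhenoTable,
    build_omega,
    fit_gblup,
    fit_multitrait_unstructured,
    gebv_across_tpe,
    predict_cells,
)
from sparsemet.markers import KinshipMatrix
from sparsemet.synthetic import compound_symmetry, simulate_met

from tests._oracles import blup_effects

CFG = MCMCConfig(n_iter=600, burn_in=200, seed=5)


def _envs(I):
    return np.array([f"E{i+1}" for i in range(I)], dtype=object)


class TestPhenoTable:
    def test_duplicate_cells_rejected(self):
        df = pd.DataFrame(
            {"line": ["L1", "L1"], "env": ["E1", "E1"], "value": [1.0, 2.0]}
        )
        with pytest.raises(ValueError, match="duplicate"):
            PhenoTable(df)

    def test_wide_roundtrip_drops_masked_cells(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 3, seed=1)
        wide = pheno.to_wide()
        wide.iloc[0, 0] = np.nan
        back = PhenoTable.from_wide(wide)
        assert len(back.frame) == len(pheno.frame) - 1


class TestBuildOmega:
    def test_identity_for_plain_gblup(self):
        om = build_omega("GBLUP", None, I=4)
        np.testing.assert_array_equal(om.omega, np.eye(4))

    def test_ce_transforms(self):
        from sparsemet.engine import MultitraitFit

        mt = MultitraitFit(
            omega_gen=np.array([[2.0, -0.3], [-0.3, 2.0]]),
            omega_res=np.array([[4.0, 0.0], [0.0, 4.0]]),
            env_ids=_envs(2),
            n_samples_used=10,
        )
        assert build_omega("GBLUP_CE_Abs", mt).omega[0, 1] == pytest.approx(0.3, abs=1e-6)
        np.testing.assert_allclose(
            build_omega("GBLUP_CE_mean", mt).omega,
            np.array([[3.0, -0.15], [-0.15, 3.0]]),
            atol=1e-6,
        )
        np.testing.assert_allclose(
            build_omega("GBLUP_CE_Res", mt).omega, 4 * np.eye(2), atol=1e-6
        )

    def test_non_psd_input_is_repaired_and_logged(self):
        from sparsemet.engine import MultitraitFit

        bad = np.array([[1.0, 2.0], [2.0, 1.0]])  # eigenvalues 3, -1
        mt = MultitraitFit(bad, np.eye(2), _envs(2), 1)
        om = build_omega("GBLUP_CE", mt)
        assert np.linalg.eigvalsh(om.omega)[0] >= 0
        assert om.repair_log["clipped_mass"] == pytest.approx(1.0, abs=1e-6)

    def test_unknown_tag_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_omega("GBLUP_XX", None, I=2)


class TestFitGBLUP:
    def test_constant_phenotype_collapses_to_mean(self, small_kinship):
        frame = pd.DataFrame(
            {
                "line": np.repeat(small_kinship.line_ids, 2),
                "env": ["E1", "E2"] * small_kinship.n_lines,
                "value": 7.0,
            }
        )
        om = build_omega("GBLUP", None, env_ids=["E1", "E2"])
        fit = fit_gblup(PhenoTable(frame), small_kinship, om, CFG)
        assert fit.mu_hat == pytest.approx(7.0, abs=0.01)
        assert np.abs(fit.gebv.values).max() < 0.05
        assert np.abs(fit.env_effects.values).max() < 0.05

    def test_deterministic_given_seed(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 3, seed=3)
        om = build_omega("GBLUP", None, env_ids=_envs(3))
        a = fit_gblup(pheno, small_kinship, om, CFG)
        b = fit_gblup(pheno, small_kinship, om, CFG)
        assert a.mu_hat == b.mu_hat
        np.testing.assert_array_equal(a.gebv.values, b.gebv.values)
        assert a.var_gen == b.var_gen

    def test_line_missing_from_training_is_named(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 3, seed=3)
        dropped = small_kinship.line_ids[4]
        frame = pheno.frame[pheno.frame["line"] != dropped]
        om = build_omega("GBLUP", None, env_ids=_envs(3))
        with pytest.raises(ValueError, match=str(dropped)):
            fit_gblup(PhenoTable(frame), small_kinship, om, CFG)

    def test_exchangeability_under_line_permutation(self, small_kinship):
        # permuting the line order permutes the GEBVs; the Gibbs chains are
        # not bitwise-identical (the eigenbasis changes), so compare posterior
        # means at Monte-Carlo accuracy
        pheno, _ = simulate_met(small_kinship, 2, seed=9)
        om = build_omega("GBLUP", None, env_ids=_envs(2))
        long_cfg = MCMCConfig(n_iter=3000, burn_in=1000, seed=5)
        fit = fit_gblup(pheno, small_kinship, om, long_cfg)
        rng = np.random.default_rng(1)
        perm = rng.permutation(small_kinship.n_lines)
        kin_p = KinshipMatrix(
            small_kinship.values[np.ix_(perm, perm)], small_kinship.line_ids[perm]
        )
        fit_p = fit_gblup(pheno, kin_p, om, long_cfg)
        merged = pd.concat([fit.gebv.rename("a"), fit_p.gebv.rename("b")], axis=1)
        assert np.corrcoef(merged["a"], merged["b"])[0, 1] > 0.995
        assert np.abs(merged["a"] - merged["b"]).max() < 0.1

    def test_fixed_variances_match_blup_oracle_sparse(self, small_kinship):
        I = 3
        pheno, _ = simulate_met(
            small_kinship, I, mu=3.0, sigma2_env=0.8, sigma2_gxe=0.4, seed=2
        )
        (part,) = cv_partitions(
            small_kinship.line_ids, _envs(I), 1, 2 / 3, "IBD", seed=4
        )
        wide = pheno.to_wide(small_kinship.line_ids, _envs(I))
        train = PhenoTable.from_wide(wide.where(part.train))
        omega = EnvCovariance(compound_symmetry(I, 0.4), _envs(I), "GBLUP_CE")
        fv = dict(env=0.8, gen=1.0, gxe=0.4, res=0.6)
        fit = fit_gblup(
            train, small_kinship, omega, MCMCConfig(3000, 500, seed=8), fixed_variances=fv
        )
        mu, L, g, gl = blup_effects(
            train.frame, small_kinship.values, omega.omega, fv,
            small_kinship.line_ids, _envs(I),
        )
        assert np.corrcoef(L, fit.env_effects.values)[0, 1] > 0.99
        assert np.corrcoef(g, fit.gebv.values)[0, 1] > 0.99
        assert np.corrcoef(gl.ravel(), fit.gxe_effects.values.ravel())[0, 1] > 0.99

    def test_hadamard_kernel_is_psd(self):
        rng = np.random.default_rng(0)
        for _ in range(5):
            a = rng.standard_normal((8, 8))
            b = rng.standard_normal((3, 3))
            K1 = a @ a.T
            K2 = b @ b.T
            grid = np.kron(K2, K1)  # full-grid Kronecker = Hadamard of expansions
            assert np.linalg.eigvalsh(grid)[0] > -1e-8


class TestPrediction:
    def _toy_fit(self):
        lines = np.array(["L1", "L2", "L3"], dtype=object)
        envs = np.array(["E1", "E2"], dtype=object)
        return GBLUPFit(
            mu_hat=5.0,
            env_effects=pd.Series([1.0, -1.0], index=envs),
            gebv=pd.Series([0.5, 0.0, -0.5], index=lines),
            gxe_effects=pd.DataFrame(np.zeros((3, 2)), index=lines, columns=envs),
            var_env=1.0,
            var_gen=1.0,
            var_gxe=1.0,
            var_res=1.0,
            method_tag="GBLUP",
            config=MCMCConfig(10, 5),
        )

    def test_hand_set_posterior_means(self):
        fit = self._toy_fit()
        cells = [(l, e) for l in ("L1", "L2", "L3") for e in ("E1", "E2")]
        preds = predict_cells(fit, cells)
        np.testing.assert_allclose(preds.values, [6.5, 4.5, 6.0, 4.0, 5.5, 3.5])

    def test_unknown_cell_rejected(self):
        with pytest.raises(KeyError):
            predict_cells(self._toy_fit(), [("L9", "E1")])
        with pytest.raises(KeyError):
            predict_cells(self._toy_fit(), [("L1", "E9")])

    def test_across_tpe_scores_are_mu_plus_gebv(self):
        fit = self._toy_fit()
        scores = gebv_across_tpe(fit)
        np.testing.assert_allclose(scores.values - fit.mu_hat, fit.gebv.values)
        np.testing.assert_allclose(scores.values, [5.5, 5.0, 4.5])


class TestMultitrait:
    def test_deterministic(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 2, seed=4)
        wide = pheno.to_wide(small_kinship.line_ids, _envs(2))
        a = fit_multitrait_unstructured(wide, small_kinship, CFG)
        b = fit_multitrait_unstructured(wide, small_kinship, CFG)
        np.testing.assert_array_equal(a.omega_gen, b.omega_gen)

    def test_single_environment_variance_decomposition(self, small_kinship):
        pheno, _ = simulate_met(
            small_kinship, 1, sigma2_env=0.0, sigma2_gxe=0.0,
            sigma2_gen=1.0, sigma2_res=1.0, omega_true=np.eye(1), seed=6,
        )
        wide = pheno.to_wide(small_kinship.line_ids, _envs(1))
        mt = fit_multitrait_unstructured(
            wide, small_kinship, MCMCConfig(1500, 500, seed=2)
        )
        total = float(mt.omega_gen[0, 0] + mt.omega_res[0, 0])
        sample_var = float(wide.iloc[:, 0].var())
        assert total == pytest.approx(sample_var, rel=0.35)

    def test_masked_cells_are_tolerated(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 3, seed=8)
        wide = pheno.to_wide(small_kinship.line_ids, _envs(3))
        (part,) = cv_partitions(
            small_kinship.line_ids, _envs(3), 1, 2 / 3, "Random", seed=3
        )
        mt = fit_multitrait_unstructured(wide.where(part.train), small_kinship, CFG)
        assert mt.omega_gen.shape == (3, 3)
        assert np.linalg.eigvalsh(mt.omega_gen)[0] > 0

    def test_empty_environment_rejected(self, small_kinship):
        pheno, _ = simulate_met(small_kinship, 2, seed=4)
        wide = pheno.to_wide(small_kinship.line_ids, _envs(2))
        wide["E2"] = np.nan
        with pytest.raises(ValueError, match="E2"):
            fit_multitrait_unstructured(wide, small_kinship, CFG)
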