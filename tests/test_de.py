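"""Poisson likelihood-ratio DE: closed-form oracle, offset invariance, calibration."""

import numpy as np
import pandas as pd
import pytest

from crossorg import SimConfig, adjust_and_flag, generate_study, normalize, poisson_de
from crossorg.de import poisson_lrt
from conftest import make_adata


def deviance_oracle(y_a, y_b, exp_a, exp_b):
    """Per-observation Poisson deviance difference, 2*sum y*log(mu1/mu0)."""
    y = np.concatenate([y_a, y_b]).astype(float)
    exp = np.concatenate([exp_a, exp_b]).astype(float)
    group = np.concatenate([np.ones_like(y_a), np.zeros_like(y_b)]).astype(bool)
    mu1 = np.where(group, y_a.sum() / exp_a.sum(), y_b.sum() / exp_b.sum()) * exp
    mu0 = (y.sum() / exp.sum()) * exp
    terms = np.zeros_like(y)
    nz = y > 0
    terms[nz] = y[nz] * np.log(mu1[nz] / mu0[nz])
    return 2.0 * terms.sum()


class TestPoissonLRT:
    def test_worked_example_statistic_and_p(self):
        """Counts 3,4,5,4 vs 0,1,2,1 with equal library sizes: LR 7.71, p 0.0055."""
        lr, p = poisson_lrt(np.array([[3], [4], [5], [4]]),
                            np.array([[0], [1], [2], [1]]),
                            np.ones(4), np.ones(4))
        assert lr[0] == pytest.approx(7.71, abs=0.005)
        assert p[0] == pytest.approx(0.0055, rel=0.02)
        assert lr[0] == pytest.approx(
            deviance_oracle(np.array([3, 4, 5, 4]), np.array([0, 1, 2, 1]),
                            np.ones(4), np.ones(4)), abs=1e-12)

    def test_equal_means_equal_libraries_gives_zero(self):
        lr, p = poisson_lrt(np.array([[2], [3]]), np.array([[3], [2]]),
                            np.ones(2), np.ones(2))
        assert lr[0] == pytest.approx(0.0, abs=1e-12)
        assert p[0] == pytest.approx(1.0)

    def test_offset_invariance_under_library_rescaling(self):
        """The offset absorbs library-size units: globally rescaling exposures
        leaves the statistic untouched, and scaling one group's exposures
        together with its counts leaves the fitted group rate ratio (hence the
        estimated fold change) untouched."""
        rng = np.random.default_rng(0)
        y_a = rng.poisson(3.0, size=(6, 5))
        y_b = rng.poisson(1.5, size=(6, 5))
        lr1, _ = poisson_lrt(y_a, y_b, np.ones(6), np.ones(6))
        lr2, _ = poisson_lrt(y_a, y_b, 3.0 * np.ones(6), 3.0 * np.ones(6))
        assert np.allclose(lr1, lr2, atol=1e-10)
        # per-group scaling: fitted rates r_g = S_g / T_g are unchanged
        r_a1 = y_a.sum(axis=0) / 6.0
        r_a2 = (2 * y_a).sum(axis=0) / (2 * np.ones(6)).sum()
        assert np.allclose(r_a1, r_a2, atol=1e-12)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_deviance_oracle_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(2, 6, size=2)
        y_a = rng.poisson(2.0, size=(n_a, 1))
        y_b = rng.poisson(2.0, size=(n_b, 1))
        exp_a = rng.uniform(0.5, 2.0, n_a)
        exp_b = rng.uniform(0.5, 2.0, n_b)
        lr, _ = poisson_lrt(y_a, y_b, exp_a, exp_b)
        expected = deviance_oracle(y_a.ravel(), y_b.ravel(), exp_a, exp_b)
        assert lr[0] == pytest.approx(expected, abs=1e-10)

    def test_matches_glm_deviance_difference(self):
        """Cross-check against an iteratively fitted Poisson GLM with offset."""
        import statsmodels.api as sm

        rng = np.random.default_rng(1)
        y_a = rng.poisson(4.0, size=(8, 1))
        y_b = rng.poisson(2.0, size=(7, 1))
        exp_a = rng.uniform(0.5, 2.0, 8)
        exp_b = rng.uniform(0.5, 2.0, 7)
        y = np.concatenate([y_a.ravel(), y_b.ravel()]).astype(float)
        g = np.concatenate([np.ones(8), np.zeros(7)])
        off = np.log(np.concatenate([exp_a, exp_b]))
        full = sm.GLM(y, sm.add_constant(g), family=sm.families.Poisson(),
                      offset=off).fit()
        null = sm.GLM(y, np.ones((15, 1)), family=sm.families.Poisson(),
                      offset=off).fit()
        lr, _ = poisson_lrt(y_a, y_b, exp_a, exp_b)
        assert lr[0] == pytest.approx(null.deviance - full.deviance, abs=1e-6)


class TestPoissonDE:
    def _toy(self):
        X = np.array([[5, 1, 2], [6, 1, 3], [1, 1, 2], [0, 1, 3]])
        return make_adata(X, condition=["disease", "disease", "control", "control"],
                          cell_type=["N"] * 4)

    def test_table_shape_and_direction(self):
        tab = poisson_de(self._toy(), cell_type="N", min_pct=0.0)
        assert list(tab.columns) == ["log2FC", "p_nominal", "p_adj", "pct_disease",
                                     "pct_control", "significant"]
        assert tab.loc["g0", "log2FC"] > 0
        assert tab.loc["g0", "pct_disease"] == 1.0
        assert tab.loc["g0", "pct_control"] == 0.5

    def test_missing_condition_is_error(self):
        data = make_adata(np.ones((4, 3)), condition=["disease"] * 4,
                          cell_type=["N"] * 4)
        with pytest.raises(ValueError, match="control"):
            poisson_de(data, cell_type="N")

    def test_expression_filter_excludes_rare_genes(self):
        X = np.ones((20, 2))
        X[:, 1] = 0
        X[0, 1] = 1  # gene present in 5% of cells only
        data = make_adata(X, condition=["disease"] * 10 + ["control"] * 10)
        tab = poisson_de(data, min_pct=0.1)
        assert "g1" not in tab.index and "g0" in tab.index


class TestAdjustAndFlag:
    def _table(self, pvals, lfcs):
        return pd.DataFrame({"log2FC": lfcs, "p_nominal": pvals,
                             "p_adj": np.nan,
                             "pct_disease": 1.0, "pct_control": 1.0,
                             "significant": False},
                            index=[f"g{i}" for i in range(len(pvals))])

    def test_bonferroni_multiplies_and_caps(self):
        tab = adjust_and_flag(self._table([0.001] + [0.2] * 9, [1.0] * 10))
        assert tab.loc["g0", "p_adj"] == pytest.approx(0.01)
        assert tab.loc["g1", "p_adj"] == 1.0

    def test_bh_step_up_worked_example(self):
        tab = adjust_and_flag(self._table([0.01, 0.02, 0.03, 0.04], [1.0] * 4),
                              method="bh")
        assert np.allclose(tab["p_adj"], 0.04)

    def test_flag_requires_both_padj_and_lfc(self):
        tab = adjust_and_flag(self._table([1e-6, 1e-6], [0.5, 0.05]),
                              alpha=0.05, lfc_min=0.1)
        assert bool(tab.loc["g0", "significant"]) is True
        assert bool(tab.loc["g1", "significant"]) is False
        assert (tab["p_adj"] >= tab["p_nominal"]).all()

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError, match="alpha"):
            adjust_and_flag(self._table([0.1], [1.0]), alpha=1.5)


class TestCalibrationAndRecovery:
    def test_type_one_error_on_null_poisson_simulation(self):
        """No planted effect, dispersion -> infinity: nominal 5% level holds."""
        cfg = SimConfig(n_shared=0, n_contrasting=0, n_specific_A=0,
                        n_specific_B=0, dispersion=1e9,
                        cell_types=(("Neurons", 150),), seed=55)
        data, _ = generate_study(cfg, "A")
        tab = poisson_de(normalize(data), cell_type="Neurons")
        rate = (tab["p_nominal"] < 0.05).mean()
        assert 0.03 <= rate <= 0.07

    def test_planted_degs_recovered_with_correct_signs(self, recovery_pair):
        """Planted |lfc|=1 genes at 300 cells/group: >=90% significant, signs right."""
        A, _, truth = recovery_pair
        tab = adjust_and_flag(poisson_de(A, cell_type="Neurons"))
        planted = truth.categories[truth.categories["sign_A"] != 0]
        sub = tab.reindex(planted.index)
        assert (sub["significant"] == True).mean() >= 0.90  # noqa: E712
        sig = sub[sub["significant"] == True]  # noqa: E712
        agree = (np.sign(sig["log2FC"]) == planted.loc[sig.index, "sign_A"]).mean()
        assert agree >= 0.95
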