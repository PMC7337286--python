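"""Preprocessing, residualization stages and the per-SNP association scan."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_variants
from protmr.gwas import (
    assoc_scan,
    preprocess_proteins,
    rank_inverse_normal,
    stage1_covariate_residualize,
    stage2_grammar_residualize,
)


class TestRankInverseNormal:
    def test_blom_scores_by_hand(self):
        # Phi^-1((r - 3/8) / (n + 1/4)) for values {5, 1, 9}
        out = rank_inverse_normal(np.array([5.0, 1.0, 9.0]))
        assert np.allclose(out, [0.0, -0.869, 0.869], atol=1e-3)

    def test_transformed_column_is_symmetric(self):
        rng = np.random.default_rng(0)
        x = rng.exponential(size=501)  # heavily skewed input
        out = rank_inverse_normal(x)
        assert abs(stats.skew(out)) < 1e-6


class TestPreprocess:
    def test_lod_threshold_is_strict(self):
        n = 250
        prot = pd.DataFrame({"keep": np.arange(n, dtype=float),
                             "drop": np.arange(n, dtype=float)})
        flags = pd.DataFrame({"keep": [True] * 200 + [False] * 50,
                              "drop": [True] * 199 + [False] * 51})
        out, dropped = preprocess_proteins(prot, flags)
        assert dropped == ["drop"] and list(out.columns) == ["keep"]

    def test_all_dropped_raises(self):
        prot = pd.DataFrame({"a": np.arange(10.0)})
        flags = pd.DataFrame({"a": [False] * 10})
        with pytest.raises(ValueError, match="all .* excluded"):
            preprocess_proteins(prot, flags)


class TestStage1:
    def test_intercept_only_centers(self):
        y = np.array([1.0, 2.0, 6.0])
        r = stage1_covariate_residualize(y, np.empty((3, 0)))
        assert np.allclose(r, y - y.mean())

    def test_perfect_fit_gives_zero_residuals(self):
        rng = np.random.default_rng(1)
        c = pd.DataFrame({"a": rng.normal(size=50), "b": rng.normal(size=50)})
        y = 2.0 + 0.5 * c["a"] - 1.2 * c["b"]
        r = stage1_covariate_residualize(y.to_numpy(), c)
        assert np.abs(r).max() < 1e-10

    def test_residuals_orthogonal_to_covariates(self):
        rng = np.random.default_rng(2)
        c = pd.DataFrame(rng.normal(size=(200, 3)), columns=list("abc"))
        y = 0.3 * c["a"].to_numpy() + rng.normal(size=200)
        r = stage1_covariate_residualize(y, c)
        cs = (c - c.mean()) / c.std(ddof=0)
        assert np.abs(cs.T.to_numpy() @ r).max() < 1e-8

    def test_known_betas_recovered_within_two_se(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        c = pd.DataFrame(rng.normal(size=(500, 2)), columns=["a", "b"])
        y = 1.0 + 0.4 * c["a"].to_numpy() - 0.7 * c["b"].to_numpy() + rng.normal(size=500)
        fit = sm.OLS(y, sm.add_constant(c)).fit()
        assert abs(fit.params["a"] - 0.4) < 2 * fit.bse["a"]
        assert abs(fit.params["b"] + 0.7) < 2 * fit.bse["b"]
        # the residualizer agrees with the reference OLS residuals
        r = stage1_covariate_residualize(y, c)
        assert np.allclose(r, fit.resid, atol=1e-10)

    def test_collinear_covariates_named(self):
        c = pd.DataFrame({"a": [1.0, 2, 3, 4], "dup": [2.0, 4, 6, 8]})
        with pytest.raises(ValueError, match="dup"):
            stage1_covariate_residualize(np.ones(4), c)


def _family_grm(n_pairs):
    """Sib-pair GRM: block diagonal of [[1, .5], [.5, 1]]."""
    from scipy.linalg import block_diag

    return block_diag(*[np.array([[1.0, 0.5], [0.5, 1.0]])] * n_pairs)


class TestStage2:
    def test_identity_grm_contract(self):
        rng = np.random.default_rng(4)
        y = rng.normal(size=100)
        res = stage2_grammar_residualize(y, np.eye(100))
        assert res.h2 == 0.0
        # residuals equal rank-normalized z-scored input on kept samples
        assert np.allclose(res.residuals, rank_inverse_normal(y[res.kept]))

    def test_h2_recovered_from_family_structure(self):
        rng = np.random.default_rng(5)
        n_pairs = 500
        grm = _family_grm(n_pairs)
        L = np.linalg.cholesky(grm + 1e-10 * np.eye(2 * n_pairs))
        g = L @ rng.standard_normal(2 * n_pairs) * np.sqrt(0.4)
        y = g + rng.standard_normal(2 * n_pairs) * np.sqrt(0.6)
        res = stage2_grammar_residualize(y, grm)
        assert abs(res.h2 - 0.4) < 0.1

    def test_single_outlier_removed(self):
        rng = np.random.default_rng(6)
        y = rng.normal(size=200)
        y[17] = 8.0  # far beyond the |z| > 4 gate
        res = stage2_grammar_residualize(y, np.eye(200))
        assert res.n_removed == 1 and not res.kept[17]

    def test_non_symmetric_grm_rejected(self):
        bad = np.eye(5)
        bad[0, 1] = 0.3
        with pytest.raises(ValueError, match="symmetric"):
            stage2_grammar_residualize(np.ones(5), bad)


class TestAssocScan:
    def test_exact_linear_relationship(self):
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 3, size=(30, 1)).astype(float)
        y = 2.0 * dos[:, 0]
        scan = assoc_scan(y, dos, make_variants(1))
        assert np.isclose(scan.loc[0, "beta1"], 2.0)
        assert np.isclose(scan.loc[0, "r2"], 1.0)

    def test_matches_per_snp_ols_oracle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(8)
        n, m = 120, 50
        dos = rng.binomial(2, 0.3, size=(n, m)).astype(float)
        y = rng.normal(size=n) + 0.2 * dos[:, 4]
        scan = assoc_scan(y, dos, make_variants(m), use_t=True)
        for j in [0, 4, 17, 49]:
            fit = sm.OLS(y, sm.add_constant(dos[:, j])).fit()
            assert abs(scan.loc[j, "beta1"] - fit.params[1]) < 1e-10
            assert abs(scan.loc[j, "se"] - fit.bse[1]) < 1e-10
            assert abs(scan.loc[j, "p"] - fit.pvalues[1]) < 1e-10

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(9)
        n, m = 400, 5000
        dos = rng.binomial(2, rng.uniform(0.1, 0.5, m), size=(n, m)).astype(float)
        y = rng.normal(size=n)
        scan = assoc_scan(y, dos, make_variants(m))
        assert stats.kstest(scan["p"], "uniform").pvalue > 0.01

    def test_p_consistent_with_beta_over_se(self):
        rng = np.random.default_rng(10)
        dos = rng.binomial(2, 0.4, size=(200, 20)).astype(float)
        y = rng.normal(size=200)
        scan = assoc_scan(y, dos, make_variants(20))
        p_re = 2 * stats.norm.sf(np.abs(scan["beta1"] / scan["se"]))
        assert np.allclose(scan["p"], p_re, rtol=1e-4)

    def test_monomorphic_flagged_not_dropped(self):
        dos = np.ones((50, 2))
        dos[:, 1] = np.random.default_rng(11).integers(0, 3, 50)
        y = np.random.default_rng(12).normal(size=50)
        scan = assoc_scan(y, dos, make_variants(2))
        assert len(scan) == 2
        assert scan.loc[0, "undefined"] and np.isnan(scan.loc[0, "beta1"])
        assert not scan.loc[1, "undefined"]
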