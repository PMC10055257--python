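"""Mixed-model machinery: transforms, PCs, kinship, REML null fits, and the
GLS scans checked against closed-form oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from scqtl import lmm
from scqtl.containers import GenotypeMatrix, KinshipMatrix


def _geno(dosages, positions=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": "1",
            "pos": positions if positions is not None else np.arange(1, m + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    donors = np.array([f"D{i}" for i in range(dosages.shape[0])], dtype=object)
    return GenotypeMatrix(donors, variants, dosages)


ANNOT = pd.DataFrame(
    [{"gene_id": "g", "chrom": "1", "tss": 5000, "strand": "+", "start": 5000, "end": 6000}]
)


def _identity_fit(n, sigma2=1.0):
    return lmm.NullFit(sigma2, 0.0, 0.0, sigma2 * np.eye(n), np.eye(n), 0.0, True)


class TestTransform:
    def test_known_values(self):
        out = lmm.inverse_normal_transform(np.array([3.1, 1.2, 2.0]))
        np.testing.assert_allclose(out, [0.9674, -0.9674, 0.0], atol=1e-4)

    def test_median_maps_to_zero_odd_n(self):
        y = np.array([5.0, 9.0, 1.0, 7.0, 3.0])
        out = lmm.inverse_normal_transform(y)
        assert out[np.argsort(y)[2]] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_pretransform_invariance(self):
        rng = np.random.default_rng(0)
        y = rng.gamma(2, size=50)
        np.testing.assert_allclose(
            lmm.inverse_normal_transform(y), lmm.inverse_normal_transform(np.log(y))
        )

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            lmm.inverse_normal_transform(np.ones(10))


class TestExpressionPcs:
    def test_rank_one_residuals_vanish(self):
        rng = np.random.default_rng(1)
        u = rng.standard_normal(20)
        v = rng.standard_normal(7)
        Y = pd.DataFrame(np.outer(u, v))
        pcs = lmm.expression_pcs(Y, k=1)
        resid = lmm.residualize(Y, pcs)
        assert np.abs(resid.to_numpy()).max() < 1e-10

    def test_residuals_orthogonal_to_pcs(self):
        rng = np.random.default_rng(2)
        Y = pd.DataFrame(rng.standard_normal((30, 12)))
        pcs = lmm.expression_pcs(Y, k=5)
        resid = lmm.residualize(Y, pcs)
        dots = pcs.to_numpy().T @ resid.to_numpy()
        assert np.abs(dots).max() < 1e-8

    def test_variance_explained_matches_eigendecomposition(self):
        rng = np.random.default_rng(3)
        Y = pd.DataFrame(rng.standard_normal((40, 10)) @ np.diag(np.arange(1, 11)))
        pcs = lmm.expression_pcs(Y, k=3)
        Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
        eigvals = np.sort(np.linalg.eigvalsh(Yc.T @ Yc))[::-1]
        pc_var = (pcs.to_numpy() ** 2).sum(axis=0)
        np.testing.assert_allclose(pc_var, eigvals[:3], rtol=1e-8)


class TestKinship:
    def test_duplicate_donors_and_symmetry(self):
        rng = np.random.default_rng(4)
        d = rng.binomial(2, 0.3, size=(20, 100)).astype(float)
        d[1] = d[0]  # duplicate genotypes
        K = lmm.compute_kinship(_geno(d))
        np.testing.assert_allclose(K.values, K.values.T, atol=1e-12)
        assert K.values[0, 1] == pytest.approx(K.values[0, 0], rel=1e-6)

    def test_independent_donors_small_offdiagonal(self):
        rng = np.random.default_rng(5)
        m = 2000
        d = rng.binomial(2, 0.3, size=(30, m)).astype(float)
        K = lmm.compute_kinship(_geno(d))
        off = K.values[~np.eye(30, dtype=bool)]
        # off-diagonals are O(1/sqrt(m))
        assert np.abs(off).mean() < 5 / np.sqrt(m)
        assert np.diag(K.values).mean() == pytest.approx(1.0, abs=0.1)


class TestNullFit:
    def test_reduces_to_ols_under_independence(self):
        rng = np.random.default_rng(6)
        n = 80
        y = rng.standard_normal(n)
        K = np.eye(n)
        w = np.ones(n)
        fit = lmm.fit_null_covariance(y, K, w)
        assert fit.sigma2_K < 0.2 and fit.sigma2_w < 0.2
        # per-SNP test matches OLS p within 1e-6 when V is (near) identity
        g = rng.binomial(2, 0.4, size=n).astype(float)
        Y = pd.DataFrame({"g": y}, index=[f"D{i}" for i in range(n)])
        G = _geno(g[:, None], positions=[5500])
        assoc = lmm.scan_cis_additive(Y, G, ANNOT.assign(gene_id="g"), {"g": _identity_fit(n)})
        ols = sm.OLS(y, sm.add_constant(g)).fit()
        assert assoc["p"].iloc[0] == pytest.approx(ols.pvalues[1], abs=1e-10)

    def test_variance_component_recovery(self):
        rng = np.random.default_rng(7)
        n = 200
        ratios = []
        for _ in range(12):
            A = rng.standard_normal((n, n // 2))
            K = A @ A.T / (n // 2)
            K = K / np.diag(K).mean()
            L = np.linalg.cholesky(K + 1e-8 * np.eye(n))
            y = L @ rng.standard_normal(n) + rng.standard_normal(n)  # s2K=1, s2e=1
            fit = lmm.fit_null_covariance(y, K, np.ones(n))
            ratios.append(fit.sigma2_K / max(fit.sigma2_e, 1e-8))
        assert 0.6 <= np.median(ratios) <= 1.6

    def test_optimum_at_least_ols(self):
        rng = np.random.default_rng(8)
        n = 60
        y = rng.standard_normal(n)
        A = rng.standard_normal((n, n))
        K = A @ A.T / n
        K /= np.diag(K).mean()
        fit = lmm.fit_null_covariance(y, K, rng.uniform(0.5, 2, n))
        ll_ols, _, _ = lmm._reml_loglik(y, np.ones((n, 1)), np.eye(n))
        assert fit.reml_loglik >= ll_ols - 1e-8


class TestAdditiveScan:
    def test_matches_direct_gls_on_toy(self):
        # 6-donor toy with a fixed, non-trivial covariance
        y = np.array([1.0, 2.0, 0.5, 3.0, 2.5, 1.5])
        g = np.array([0.0, 1.0, 0.0, 2.0, 2.0, 1.0])
        n = 6
        V = 0.5 * np.eye(n) + 0.3 * np.ones((n, n)) + np.diag(np.arange(1, 7) / 10)
        fit = lmm.NullFit(1.0, 0.0, 0.0, V, np.linalg.cholesky(V), 0.0, True)
        Y = pd.DataFrame({"g": y}, index=[f"D{i}" for i in range(n)])
        G = _geno(g[:, None], positions=[5500])
        assoc = lmm.scan_cis_additive(Y, G, ANNOT, {"g": fit})
        # oracle: explicit feasible GLS with V
        X = np.column_stack([np.ones(n), g])
        Vi = np.linalg.inv(V)
        XtVi = X.T @ Vi
        beta = np.linalg.solve(XtVi @ X, XtVi @ y)
        r = y - X @ beta
        s2 = (r @ Vi @ r) / (n - 2)
        se = np.sqrt(s2 * np.linalg.inv(XtVi @ X)[1, 1])
        assert assoc["beta"].iloc[0] == pytest.approx(beta[1], rel=1e-6)
        assert assoc["se"].iloc[0] == pytest.approx(se, rel=1e-6)

    def test_identity_covariance_equals_ols_exactly(self):
        rng = np.random.default_rng(9)
        n = 50
        y = rng.standard_normal(n)
        g = rng.binomial(2, 0.3, n).astype(float)
        Y = pd.DataFrame({"g": y}, index=[f"D{i}" for i in range(n)])
        G = _geno(g[:, None], positions=[5500])
        assoc = lmm.scan_cis_additive(Y, G, ANNOT, {"g": _identity_fit(n, 2.7)})
        ols = sm.OLS(y, sm.add_constant(g)).fit()
        assert assoc["beta"].iloc[0] == pytest.approx(ols.params[1], abs=1e-10)
        assert assoc["se"].iloc[0] == pytest.approx(ols.bse[1], abs=1e-10)

    def test_cis_window_excludes_distal_variant(self):
        rng = np.random.default_rng(10)
        n = 30
        g = rng.binomial(2, 0.4, size=(n, 2)).astype(float)
        Y = pd.DataFrame({"g": rng.standard_normal(n)}, index=[f"D{i}" for i in range(n)])
        G = _geno(g, positions=[5500, 5000 + 2_000_000])
        assoc = lmm.scan_cis_additive(Y, G, ANNOT, {"g": _identity_fit(n)}, window=1_000_000)
        assert list(assoc["variant"]) == ["v0"]

    def test_allele_relabeling_flips_sign_only(self):
        rng = np.random.default_rng(11)
        n = 40
        g = rng.binomial(2, 0.3, n).astype(float)
        y = 0.4 * g + rng.standard_normal(n)
        Y = pd.DataFrame({"g": y}, index=[f"D{i}" for i in range(n)])
        a = lmm.scan_cis_additive(Y, _geno(g[:, None], positions=[5500]), ANNOT,
                                  {"g": _identity_fit(n)})
        b = lmm.scan_cis_additive(Y, _geno((2 - g)[:, None], positions=[5500]), ANNOT,
                                  {"g": _identity_fit(n)})
        assert a["beta"].iloc[0] == pytest.approx(-b["beta"].iloc[0], rel=1e-10)
        assert a["p"].iloc[0] == pytest.approx(b["p"].iloc[0], rel=1e-10)

    def test_tss_distance_strand_aware(self):
        rng = np.random.default_rng(12)
        n = 30
        g = rng.binomial(2, 0.4, n).astype(float)
        Y = pd.DataFrame({"g": rng.standard_normal(n)}, index=[f"D{i}" for i in range(n)])
        G = _geno(g[:, None], positions=[6000])
        minus = ANNOT.copy()
        minus["strand"] = "-"
        plus_d = lmm.scan_cis_additive(Y, G, ANNOT, {"g": _identity_fit(n)})["tss_dist"].iloc[0]
        minus_d = lmm.scan_cis_additive(Y, G, minus, {"g": _identity_fit(n)})["tss_dist"].iloc[0]
        assert plus_d == 1000 and minus_d == -1000


class TestInteractionScan:
    def _setup(self, seed=13, n=80, beta_gd=0.0):
        rng = np.random.default_rng(seed)
        g = rng.binomial(2, 0.4, n).astype(float)
        dis = np.array(["ILD"] * (n // 2) + ["control"] * (n - n // 2), dtype=object)
        x = (dis == "ILD").astype(float)
        y = 0.2 * g + 0.3 * x + beta_gd * g * x + rng.standard_normal(n)
        idx = pd.Index([f"D{i}" for i in range(n)])
        Y = pd.DataFrame({"g": y}, index=idx)
        pcs = pd.DataFrame(rng.standard_normal((n, 2)), index=idx, columns=["PC1", "PC2"])
        G = _geno(g[:, None], positions=[5500])
        return Y, G, pd.Series(dis, index=idx), pcs

    def test_disease_coding_swap_preserves_statistic(self):
        Y, G, dis, pcs = self._setup(beta_gd=0.8)
        fits = {"g": _identity_fit(len(Y))}
        a = lmm.scan_cis_interaction(Y, G, ANNOT, dis, pcs, fits, min_donors_per_group=5)
        swapped = dis.map({"ILD": "control", "control": "ILD"})
        b = lmm.scan_cis_interaction(Y, G, ANNOT, swapped, pcs, fits, min_donors_per_group=5)
        assert abs(a["stat"].iloc[0]) == pytest.approx(abs(b["stat"].iloc[0]), rel=1e-8)

    def test_group_maf_exclusion(self):
        Y, G, dis, pcs = self._setup()
        # make the variant rare in controls: MAF 0.04 among 40 controls
        g = G.dosages[:, 0].copy()
        ctrl = (dis == "control").to_numpy()
        g[ctrl] = 0.0
        g[np.flatnonzero(ctrl)[:3]] = 1.0  # 3/80 alleles < 5%
        G2 = _geno(g[:, None], positions=[5500])
        out = lmm.scan_cis_interaction(Y, G2, ANNOT, dis, pcs,
                                       {"g": _identity_fit(len(Y))}, min_donors_per_group=5)
        assert out.empty

    def test_matches_ols_interaction_coefficient(self):
        Y, G, dis, pcs = self._setup(beta_gd=0.8)
        out = lmm.scan_cis_interaction(Y, G, ANNOT, dis, pcs,
                                       {"g": _identity_fit(len(Y))}, min_donors_per_group=5)
        x = (dis == "ILD").astype(float).to_numpy()
        g = G.dosages[:, 0]
        X = sm.add_constant(np.column_stack([pcs.to_numpy(), g, x, g * x]))
        ols = sm.OLS(Y["g"].to_numpy(), X).fit()
        assert out["beta"].iloc[0] == pytest.approx(ols.params[-1], abs=1e-8)
        assert out["se"].iloc[0] == pytest.approx(ols.bse[-1], abs=1e-8)

    def test_too_few_donors_per_group_rejected(self):
        Y, G, dis, pcs = self._setup()
        dis.iloc[: len(dis) - 5] = "ILD"
        with pytest.raises(ValueError):
            lmm.scan_cis_interaction(Y, G, ANNOT, dis, pcs, {"g": _identity_fit(len(Y))})
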