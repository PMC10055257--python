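"""Cis-eQTL scans with a two-random-effect linear mixed model.

Per cell type and gene the pipeline (i) rank-based inverse-normal transforms
donor-level expression, (ii) removes expression principal components, (iii)
fits the null covariance V = sigma2_K * K + sigma2_w * diag(1/nCells) +
sigma2_e * I by REML once per gene, and (iv) tests each cis variant by
generalized least squares with V fixed (the EMMAX approximation): the model
is whitened with the Cholesky factor of V-hat and the test is an ordinary
Wald t-test on the whitened design, so with V proportional to the identity
the scan reduces exactly to OLS.

Interaction scans keep the PCs as fixed effects (not regressed out, since
disease status can correlate with expression PCs) and test the
dose x disease coefficient.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import norm, rankdata
from scipy.stats import t as t_dist

from .containers import GenotypeMatrix, KinshipMatrix

log = logging.getLogger(__name__)


def inverse_normal_transform(y: np.ndarray) -> np.ndarray:
    """Rank-based inverse normal transform, Phi^-1((rank - 0.5)/n).

    Average ranks for ties; raises on degenerate (all-tied) input.
    """
    y = np.asarray(y, dtype=float)
    if y.ndim != 1 or len(y) < 3:
        raise ValueError("need a 1-d vector with >= 3 values")
    if np.unique(y).size < 2:
        raise ValueError("degenerate gene: all values tied")
    r = rankdata(y, method="average")
    return norm.ppf((r - 0.5) / len(y))


def transform_matrix(Y: pd.DataFrame) -> pd.DataFrame:
    """Column-wise inverse normal transform; all-tied genes dropped with a warning."""
    cols = {}
    dropped = []
    for g in Y.columns:
        v = Y[g].to_numpy(dtype=float)
        if np.unique(v).size < 2:
            dropped.append(g)
            continue
        cols[g] = inverse_normal_transform(v)
    if dropped:
        warnings.warn(f"dropped {len(dropped)} constant genes before transform")
    return pd.DataFrame(cols, index=Y.index)


def expression_pcs(Y: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Top-k principal component scores of the donor x gene matrix (SVD on
    column-centered data); k is capped at min(k, n_donors - 2, n_genes)."""
    n = Y.shape[0]
    if n < 5:
        raise ValueError("need at least 5 donors for expression PCs")
    k = int(min(k, n - 2, Y.shape[1]))
    Yc = Y.to_numpy() - Y.to_numpy().mean(axis=0)
    U, s, _ = np.linalg.svd(Yc, full_matrices=False)
    scores = U[:, :k] * s[:k]
    return pd.DataFrame(scores, index=Y.index, columns=[f"PC{i+1}" for i in range(k)])


def residualize(Y: pd.DataFrame, pcs: pd.DataFrame) -> pd.DataFrame:
    """Residuals of each gene on [intercept, PCs]."""
    X = np.column_stack([np.ones(len(Y)), pcs.to_numpy()])
    B, *_ = np.linalg.lstsq(X, Y.to_numpy(), rcond=None)
    return pd.DataFrame(Y.to_numpy() - X @ B, index=Y.index, columns=Y.columns)


def compute_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """Genomic relationship matrix K = X_std X_std^T / m from standardized dosages."""
    X = G.dosages
    if X.shape[1] == 0:
        raise ValueError("no variants for kinship")
    if X.shape[1] < 10:
        warnings.warn(f"kinship from only {X.shape[1]} variants is unstable")
    Xc = X - X.mean(axis=0)
    sd = Xc.std(axis=0)
    poly = sd > 0
    Xs = Xc[:, poly] / sd[poly]
    K = (Xs @ Xs.T) / Xs.shape[1]
    K = (K + K.T) / 2
    # tiny ridge keeps the matrix numerically PSD
    K += 1e-8 * np.eye(K.shape[0])
    return KinshipMatrix(G.donors, K)


@dataclass
class NullFit:
    """Fitted null covariance for one gene: V = sigma2_e * (I + gK*K + gw*W)."""

    sigma2_e: float
    sigma2_K: float
    sigma2_w: float
    V: np.ndarray
    L: np.ndarray          # Cholesky factor of Sigma = V / sigma2_e
    reml_loglik: float
    converged: bool

    def whiten(self, M: np.ndarray) -> np.ndarray:
        """Solve L z = M, i.e. decorrelate rows of M under Sigma-hat."""
        from scipy.linalg import solve_triangular

        return solve_triangular(self.L, M, lower=True)


def _reml_loglik(y: np.ndarray, X: np.ndarray, Sigma: np.ndarray) -> tuple[float, float, np.ndarray]:
    """Restricted log-likelihood with the residual scale profiled out."""
    n, p = X.shape
    L = np.linalg.cholesky(Sigma)
    from scipy.linalg import solve_triangular

    yw = solve_triangular(L, y, lower=True)
    Xw = solve_triangular(L, X, lower=True)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    r = yw - Xw @ beta
    rss = float(r @ r)
    sigma2 = rss / (n - p)
    logdet_S = 2.0 * np.log(np.diag(L)).sum()
    sign, logdet_X = np.linalg.slogdet(XtX)
    ll = -0.5 * ((n - p) * (np.log(2 * np.pi * sigma2) + 1.0) + logdet_S + logdet_X)
    return ll, sigma2, L


def fit_null_covariance(
    y: np.ndarray,
    K: np.ndarray,
    w: np.ndarray,
    max_iter: int = 200,
) -> NullFit:
    """REML fit of V = sigma2_K K + sigma2_w diag(w) + sigma2_e I, intercept-only
    fixed effects. Optimizes the two variance ratios on the log scale with the
    residual variance profiled out; the OLS boundary (both ratios zero) is
    always evaluated, so the returned likelihood never falls below it.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = np.ones((n, 1))
    W = np.asarray(w, dtype=float)

    def sigma_of(log_g):
        gK, gw = np.exp(log_g)
        return np.eye(n) + gK * K + gw * np.diag(W)

    def neg_ll(log_g):
        log_g = np.clip(log_g, -12.0, 12.0)
        try:
            ll, _, _ = _reml_loglik(y, X, sigma_of(log_g))
        except np.linalg.LinAlgError:
            return 1e10
        return -ll

    ll_ols, s2_ols, L_ols = _reml_loglik(y, X, np.eye(n))
    best = {"ll": ll_ols, "gK": 0.0, "gw": 0.0, "converged": True}
    for start in ([0.0, 0.0], [1.0, -1.0], [-1.0, 1.0]):
        res = optimize.minimize(
            neg_ll, start, method="Nelder-Mead",
            options={"maxiter": max_iter, "xatol": 1e-4, "fatol": 1e-7},
        )
        if -res.fun > best["ll"] + 1e-10:
            gK, gw = np.exp(np.clip(res.x, -12.0, 12.0))
            best = {"ll": -res.fun, "gK": gK, "gw": gw, "converged": bool(res.success)}
    if best["gK"] == 0.0 and best["gw"] == 0.0:
        return NullFit(s2_ols, 0.0, 0.0, s2_ols * np.eye(n), np.eye(n), ll_ols, True)
    Sigma = np.eye(n) + best["gK"] * K + best["gw"] * np.diag(W)
    ll, sigma2, L = _reml_loglik(y, X, Sigma)
    if not np.isfinite(ll):
        warnings.warn("REML did not converge; falling back to OLS covariance")
        return NullFit(s2_ols, 0.0, 0.0, s2_ols * np.eye(n), np.eye(n), ll_ols, False)
    return NullFit(
        sigma2_e=sigma2,
        sigma2_K=sigma2 * best["gK"],
        sigma2_w=sigma2 * best["gw"],
        V=sigma2 * Sigma,
        L=L,
        reml_loglik=ll,
        converged=best["converged"],
    )


def _gls_scan(yw: np.ndarray, Xw_base: np.ndarray, gw: np.ndarray, dof: int):
    """Batched feasible-GLS t-tests for one whitened regressor per column of gw.

    Xw_base holds the whitened nuisance columns (intercept, optionally PCs and
    main effects); gw the whitened test regressors. Returns beta, se, t, p.
    """
    m = gw.shape[1]
    p = Xw_base.shape[1] + 1
    beta = np.empty(m)
    se = np.empty(m)
    yty = float(yw @ yw)
    Bt_y = Xw_base.T @ yw
    BtB = Xw_base.T @ Xw_base
    BtB_inv = np.linalg.inv(BtB)
    for j in range(m):
        g = gw[:, j]
        Btg = Xw_base.T @ g
        gtg = float(g @ g)
        gty = float(g @ yw)
        # block inversion: effective g after projecting out base columns
        tmp = BtB_inv @ Btg
        s_gg = gtg - float(Btg @ tmp)
        if s_gg <= 1e-12:
            beta[j], se[j] = 0.0, np.inf
            continue
        b_g = (gty - float(Btg @ (BtB_inv @ Bt_y))) / s_gg
        b_base = BtB_inv @ (Bt_y - Btg * b_g)
        rss = yty - 2 * (b_base @ Bt_y + b_g * gty) + (
            b_base @ (BtB @ b_base) + 2 * b_g * float(Btg @ b_base) + b_g ** 2 * gtg
        )
        rss = max(rss, 1e-300)
        sigma2 = rss / dof
        beta[j] = b_g
        se[j] = np.sqrt(sigma2 / s_gg)
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = beta / se
    pval = 2 * t_dist.sf(np.abs(tstat), dof)
    pval = np.clip(pval, np.finfo(float).tiny, 1.0)
    return beta, se, tstat, pval


def cis_window_mask(variants: pd.DataFrame, gene: pd.Series, window: int) -> np.ndarray:
    """Variants within ``window`` bp of the gene body (strand-agnostic)."""
    same_chrom = variants["chrom"].astype(str) == str(gene["chrom"])
    lo, hi = gene["start"] - window, gene["end"] + window
    return (same_chrom & (variants["pos"] >= lo) & (variants["pos"] <= hi)).to_numpy()


def scan_cis_additive(
    Y_resid: pd.DataFrame,
    G: GenotypeMatrix,
    annotation: pd.DataFrame,
    null_fits: dict[str, NullFit],
    window: int = 1_000_000,
    cell_type: str = "NA",
    n_covar_regressed: int = 0,
    pcs: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Additive cis scan: per gene, GLS Wald tests of each cis variant.

    When ``pcs`` is given, genotypes are residualized on the same covariates
    that were regressed out of Y (the Frisch-Waugh-Lovell construction, so
    the test equals the full model with PCs as fixed effects); otherwise the
    genotype's chance correlation with the removed PC space deflates the
    statistic. ``n_covar_regressed`` counts those covariates, so the t-test
    has n - 2 - that many degrees of freedom.
    """
    annot = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    Gd = G.subset_donors(Y_resid.index)
    dosages = Gd.dosages
    if pcs is not None:
        P = np.column_stack([np.ones(len(Y_resid)), pcs.loc[Y_resid.index].to_numpy()])
        B, *_ = np.linalg.lstsq(P, dosages, rcond=None)
        dosages = dosages - P @ B
        n_covar_regressed = max(n_covar_regressed, pcs.shape[1])
    rows = []
    for gene in Y_resid.columns:
        if gene not in annot.index:
            continue
        ga = annot.loc[gene]
        mask = cis_window_mask(Gd.variants, ga, window)
        if not mask.any():
            log.info("gene %s: no cis variants in window, skipped", gene)
            continue
        fit = null_fits[gene]
        y = Y_resid[gene].to_numpy()
        n = len(y)
        dof = n - 2 - n_covar_regressed
        yw = fit.whiten(y)
        ones_w = fit.whiten(np.ones((n, 1)))
        gsub = dosages[:, mask]
        gw = fit.whiten(gsub)
        beta, se, tstat, pval = _gls_scan(yw, ones_w, gw, dof)
        vsub = Gd.variants.loc[mask]
        sign = 1 if ga["strand"] == "+" else -1
        tss_dist = sign * (vsub["pos"].to_numpy() - ga["tss"])
        for i, (_, v) in enumerate(vsub.iterrows()):
            rows.append(
                {
                    "cell_type": cell_type, "gene": gene, "variant": v["variant_id"],
                    "chrom": v["chrom"], "pos": v["pos"], "term": "additive",
                    "beta": beta[i], "se": se[i], "stat": tstat[i], "p": pval[i],
                    "tss_dist": int(tss_dist[i]), "n_donors": n,
                }
            )
    return pd.DataFrame(rows)


def scan_cis_interaction(
    Y: pd.DataFrame,
    G: GenotypeMatrix,
    annotation: pd.DataFrame,
    disease: pd.Series,
    pcs: pd.DataFrame,
    null_fits: dict[str, NullFit],
    window: int = 1_000_000,
    cell_type: str = "NA",
    group_maf_min: float = 0.05,
    min_donors_per_group: int = 10,
) -> pd.DataFrame:
    """Genotype x disease interaction scan.

    Fixed effects are [intercept, PCs, dose, disease, dose x disease]; the
    Wald t-test is on the interaction coefficient under the gene's null
    covariance. Variants with per-group MAF <= ``group_maf_min`` among the
    analyzed donors are dropped (the post-hoc per-cell-type rule; the
    cohort-wide pre-filter uses the same routine on the full panel).
    """
    x_dis = (disease.loc[Y.index].astype(str) == "ILD").astype(float).to_numpy()
    n_case, n_ctrl = int(x_dis.sum()), int((1 - x_dis).sum())
    if min(n_case, n_ctrl) < min_donors_per_group:
        raise ValueError(
            f"cell type {cell_type}: {n_case} ILD / {n_ctrl} control donors, "
            f"need >= {min_donors_per_group} each"
        )
    annot = annotation.set_index("gene_id") if "gene_id" in annotation.columns else annotation
    Gd = G.subset_donors(Y.index)
    P = pcs.loc[Y.index].to_numpy()
    # guard against PCs confounded with disease (rank deficiency): add PCs
    # one at a time and keep only those that increase the design rank
    design = np.column_stack([np.ones(len(Y)), x_dis])
    kept_cols = []
    for j in range(P.shape[1]):
        cand = np.column_stack([design, P[:, j]])
        if np.linalg.matrix_rank(cand, tol=1e-8) > np.linalg.matrix_rank(design, tol=1e-8):
            design = cand
            kept_cols.append(j)
        else:
            log.warning("cell type %s: PC%d collinear with disease, dropped", cell_type, j + 1)
    P = P[:, kept_cols]

    # per-group MAF among analyzed donors
    with np.errstate(invalid="ignore"):
        p_case = Gd.dosages[x_dis == 1].mean(axis=0) / 2
        p_ctrl = Gd.dosages[x_dis == 0].mean(axis=0) / 2
    maf_case = np.minimum(p_case, 1 - p_case)
    maf_ctrl = np.minimum(p_ctrl, 1 - p_ctrl)
    maf_ok = (maf_case > group_maf_min) & (maf_ctrl > group_maf_min)

    rows = []
    for gene in Y.columns:
        if gene not in annot.index:
            continue
        ga = annot.loc[gene]
        mask = cis_window_mask(Gd.variants, ga, window) & maf_ok
        if not mask.any():
            continue
        fit = null_fits[gene]
        y = Y[gene].to_numpy()
        n = len(y)
        yw = fit.whiten(y)
        gsub = Gd.dosages[:, mask]
        gw_all = fit.whiten(gsub)
        vsub = Gd.variants.loc[mask]
        dof = n - (3 + P.shape[1] + 1)
        for i, (_, v) in enumerate(vsub.iterrows()):
            g = gsub[:, i]
            Xbase = np.column_stack([np.ones(n), P, g, x_dis])
            Xw = fit.whiten(Xbase)
            inter_w = fit.whiten((g * x_dis)[:, None])
            beta, se, tstat, pval = _gls_scan(yw, Xw, inter_w, dof)
            rows.append(
                {
                    "cell_type": cell_type, "gene": gene, "variant": v["variant_id"],
                    "chrom": v["chrom"], "pos": v["pos"], "term": "interaction",
                    "beta": beta[0], "se": se[0], "stat": tstat[0], "p": pval[0],
                    "tss_dist": int((1 if ga["strand"] == "+" else -1) * (v["pos"] - ga["tss"])),
                    "n_donors": n,
                    "maf_case": maf_case[np.flatnonzero(mask)[i]],
                    "maf_ctrl": maf_ctrl[np.flatnonzero(mask)[i]],
                }
            )
    return pd.DataFrame(rows)


def fit_null_per_gene(
    Y: pd.DataFrame, K: KinshipMatrix, n_cells: pd.Series
) -> dict[str, NullFit]:
    """Fit the two-variance-component null for every gene of one cell type."""
    Ka = K.align(Y.index)
    w = 1.0 / n_cells.loc[Y.index].to_numpy(dtype=float)
    return {g: fit_null_covariance(Y[g].to_numpy(), Ka, w) for g in Y.columns}
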