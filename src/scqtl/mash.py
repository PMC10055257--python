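"""Empirical-Bayes multivariate shrinkage of multi-cell-type effect estimates.

Models the vector of per-cell-type effect estimates b-hat_i for association i
as b-hat_i ~ N(b_i, S_i^2) with prior b_i ~ sum_{k,l} pi_{k,l} N(0, omega_l
U_k) plus a point mass at zero; covariance components U_k combine canonical
patterns (identity, per-cell-type singletons, equal sharing) with data-driven
matrices learned from the strongest signals by PCA and extreme deconvolution.
Mixture weights are fit by EM on a random subset of associations; posteriors
give condition-wise shrunken means, standard deviations and the local false
sign rate (lfsr), the posterior probability that the reported sign is wrong
or the effect is null.

Effects are modeled on the effect-size scale (the EE parameterization).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import norm

_LOG2PI = np.log(2 * np.pi)


def _mixture_weight_em(
    logL: np.ndarray,
    lam: np.ndarray,
    max_iter: int = 2000,
    tol: float = 1e-9,
) -> tuple[np.ndarray, list[float]]:
    """Fit mixture weights by SQUAREM-accelerated penalized EM.

    ``logL[i, m]`` is the log-likelihood of observation i under component m;
    ``lam`` are Dirichlet pseudo-counts (lam > 1 biases a component up, used
    to break the ridge between a point-mass null and vanishing-scale slabs).
    Accelerated steps that would decrease the penalized objective fall back
    to the plain EM step, so the accepted objective is non-decreasing.
    """
    n, M = logL.shape

    def em_step(pi):
        """One EM update; also returns the penalized objective AT ``pi``."""
        w = logL + np.log(pi + 1e-300)
        mx = w.max(axis=1, keepdims=True)
        lse = mx[:, 0] + np.log(np.exp(w - mx).sum(axis=1))
        obj = float(lse.sum() + ((lam - 1) * np.log(pi + 1e-300)).sum())
        resp = np.exp(w - lse[:, None])
        new = resp.sum(axis=0) + lam - 1.0
        new = np.maximum(new, 0.0)
        return new / new.sum(), obj

    pi = np.full(M, 1.0 / M)
    trace: list[float] = []
    for _ in range(max_iter):
        p1, obj0 = em_step(pi)
        p2, obj1 = em_step(p1)
        if trace and obj0 < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError("EM penalized objective decreased (bug)")
        trace.append(obj0)
        r = p1 - pi
        v = (p2 - p1) - r
        vv = float(v @ v)
        p_new = p2
        if vv > 0:
            alpha = -np.sqrt(float(r @ r) / vv)
            acc = pi - 2 * alpha * r + alpha ** 2 * v
            acc = np.maximum(acc, 0.0)
            s = acc.sum()
            if s > 0:
                cand, obj_acc = em_step(acc / s)
                # accept the accelerated point only if it did not hurt
                if obj_acc >= obj1:
                    p_new = cand
        delta = np.abs(p_new - pi).max()
        converged = bool(trace) and len(trace) > 1 and (
            (obj0 - trace[-2]) < tol * max(1.0, abs(obj0)) and delta < 1e-7
        )
        pi = p_new
        if converged:
            break
    return pi, trace


# ---------------------------------------------------------------------------
# univariate adaptive shrinkage (condition-by-condition)

def _ash_grid(b: np.ndarray, s: np.ndarray) -> np.ndarray:
    lo = s.min() / 10.0
    hi = max(2.0 * np.abs(b).max(), lo * 2)
    n = int(np.ceil(np.log2(hi / lo) / 0.5)) + 1  # sqrt(2)-spaced
    return lo * (np.sqrt(2.0) ** np.arange(n))


def ash_univariate(
    b: np.ndarray,
    s: np.ndarray,
    grid: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-9,
) -> pd.DataFrame:
    """Adaptive shrinkage of one condition's estimates; returns posterior
    summaries including the lfsr.

    The prior is pi_0 delta_0 + sum_j pi_j N(0, sigma_j^2) on a geometric grid
    spanning [min(s)/10, 2 max|b|], fit by penalized EM with a null-biased
    Dirichlet prior (pseudo-count ``null_penalty`` on the point mass), which
    resolves the likelihood ridge between the null and near-zero slabs in
    favor of the null. The penalized objective must not decrease.
    """
    b = np.asarray(b, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(s <= 0):
        raise ValueError("standard errors must be positive")
    sig = _ash_grid(b, s) if grid is None else np.asarray(grid, dtype=float)
    # component marginal variances: null (0) + slab grid
    var = np.concatenate([[0.0], sig ** 2])          # (J+1,)
    marg_var = s[:, None] ** 2 + var[None, :]        # (n, J+1)
    loglik = -0.5 * (np.log(2 * np.pi * marg_var) + b[:, None] ** 2 / marg_var)
    lam = np.ones(len(var))
    lam[0] = 10.0                                    # null-biased prior
    pi, _ = _mixture_weight_em(loglik, lam, max_iter=max_iter, tol=tol)
    w = loglik + np.log(pi + 1e-300)
    m = w.max(axis=1, keepdims=True)
    lse = m[:, 0] + np.log(np.exp(w - m).sum(axis=1))
    resp = np.exp(w - lse[:, None])
    # posterior per observation
    post_var = var[None, :] * s[:, None] ** 2 / marg_var   # slab conditional var
    shrink = var[None, :] / marg_var
    post_mean_j = shrink * b[:, None]
    neg = np.zeros_like(resp[:, 0])
    pos = np.zeros_like(neg)
    point = resp[:, 0]
    sd_j = np.sqrt(np.maximum(post_var, 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        cdf0 = norm.cdf(0.0, loc=post_mean_j[:, 1:], scale=np.maximum(sd_j[:, 1:], 1e-300))
    neg = (resp[:, 1:] * cdf0).sum(axis=1)
    pos = (resp[:, 1:] * (1 - cdf0)).sum(axis=1)
    lfsr = np.minimum(neg + point, pos + point)
    post_mean = (resp[:, 1:] * post_mean_j[:, 1:]).sum(axis=1)
    second = (resp[:, 1:] * (post_var[:, 1:] + post_mean_j[:, 1:] ** 2)).sum(axis=1)
    post_sd = np.sqrt(np.maximum(second - post_mean ** 2, 0.0))
    out = pd.DataFrame(
        {"post_mean": post_mean, "post_sd": post_sd, "lfsr": np.clip(lfsr, 0, 1),
         "pi0_post": point}
    )
    out.attrs["pi"] = pi            # fitted weights: [null, slab grid...]
    out.attrs["grid_sd"] = sig
    return out


# ---------------------------------------------------------------------------
# multivariate model

@dataclass
class MultiConditionStats:
    """Effect estimates and standard errors across conditions (cell types)."""

    ids: pd.Index                 # association ids (e.g. "gene:variant")
    Bhat: np.ndarray              # (n, R)
    S: np.ndarray                 # (n, R), > 0 where observed
    conditions: list[str]

    def __post_init__(self) -> None:
        self.Bhat = np.asarray(self.Bhat, dtype=float)
        self.S = np.asarray(self.S, dtype=float)
        if self.Bhat.shape != self.S.shape:
            raise ValueError("Bhat and S shapes differ")
        if self.Bhat.shape[1] != len(self.conditions):
            raise ValueError("condition count mismatch")
        obs = ~np.isnan(self.Bhat)
        if np.any(self.S[obs] <= 0):
            raise ValueError("standard errors must be positive where observed")

    @property
    def n(self) -> int:
        return self.Bhat.shape[0]

    @property
    def R(self) -> int:
        return self.Bhat.shape[1]

    def zscores(self) -> np.ndarray:
        return self.Bhat / self.S

    @classmethod
    def from_assoc(cls, assoc: pd.DataFrame, fill_se: float = 10.0) -> "MultiConditionStats":
        """Pivot a long AssocSummary frame into condition-wise matrices.

        Associations missing in a cell type get b=0 with a large standard
        error ``fill_se`` (an effectively uninformative observation).
        """
        assoc = assoc.assign(assoc_id=assoc["gene"] + ":" + assoc["variant"])
        B = assoc.pivot_table(index="assoc_id", columns="cell_type", values="beta")
        S = assoc.pivot_table(index="assoc_id", columns="cell_type", values="se")
        conditions = sorted(B.columns)
        B = B[conditions]
        S = S[conditions]
        miss = B.isna()
        return cls(
            ids=B.index,
            Bhat=B.fillna(0.0).to_numpy(),
            S=S.where(~miss, fill_se).to_numpy(),
            conditions=list(conditions),
        )


def estimate_null_correlation(stats: MultiConditionStats, z_max: float = 2.0) -> np.ndarray:
    """Correlation of estimation errors across conditions, from null-looking rows.

    Associations whose largest |z| stays below ``z_max`` are treated as null;
    the correlation of their z-scores estimates the cross-condition error
    correlation (nonzero whenever conditions share donors, as pseudo-bulk
    cell types do). Falls back to the identity if too few rows qualify.
    """
    Z = stats.zscores()
    null_rows = np.abs(Z).max(axis=1) < z_max
    if null_rows.sum() < 5 * stats.R:
        warnings.warn("too few null-looking rows; using identity error correlation")
        return np.eye(stats.R)
    V = np.corrcoef(Z[null_rows].T)
    V = (V + V.T) / 2
    w, Q = np.linalg.eigh(V)
    V = (Q * np.maximum(w, 1e-6)) @ Q.T
    d = np.sqrt(np.diag(V))
    return V / np.outer(d, d)


def canonical_covariances(R: int) -> dict[str, np.ndarray]:
    """Identity, one singleton per condition, and the all-ones equal-sharing matrix."""
    if R < 2:
        raise ValueError("need at least 2 conditions")
    out = {"identity": np.eye(R)}
    for r in range(R):
        U = np.zeros((R, R))
        U[r, r] = 1.0
        out[f"singleton_{r}"] = U
    out["equal_effects"] = np.ones((R, R))
    return out


def _psd_clip(U: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    w, V = np.linalg.eigh((U + U.T) / 2)
    w = np.maximum(w, floor)
    return (V * w) @ V.T


def datadriven_covariances(
    Z: np.ndarray, n_pcs: int = 5, ed_iters: int = 50
) -> dict[str, np.ndarray]:
    """Data-driven covariance components from the strong-association z-scores.

    A rank-``n_pcs`` PCA reconstruction of the z-score second-moment matrix
    seeds extreme deconvolution (EM re-estimating mixture covariances under
    unit measurement error), run for ``ed_iters`` iterations with a PSD floor.
    """
    Z = np.asarray(Z, dtype=float)
    n, R = Z.shape
    if n < 2 * R:
        warnings.warn(f"only {n} strong associations for {R} conditions; "
                      "data-driven covariances may be unstable")
    n_pcs = min(n_pcs, R)
    M = (Z.T @ Z) / n
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    U_pca = (V[:, :n_pcs] * np.maximum(w[:n_pcs], 0)) @ V[:, :n_pcs].T
    inits = {"tPCA": _psd_clip(U_pca)}
    for j in range(n_pcs):
        inits[f"PCA_{j+1}"] = _psd_clip(max(w[j], 0.0) * np.outer(V[:, j], V[:, j]))
    ed_U, ed_obj = extreme_deconvolution(Z, list(inits.values()), n_iter=ed_iters)
    out = {}
    for (name, _), U in zip(inits.items(), ed_U):
        out[f"ED_{name}"] = U
    return out


def extreme_deconvolution(
    Z: np.ndarray,
    U_init: list[np.ndarray],
    n_iter: int = 50,
    eig_floor: float = 1e-8,
) -> tuple[list[np.ndarray], list[float]]:
    """EM covariance re-estimation under Z_i ~ N(0, U_k + I) per component.

    Means are fixed at zero; mixture weights and covariances are updated; the
    observed-data log-likelihood is non-decreasing (up to the PSD floor).
    Returns the refined covariances and the objective trace.
    """
    n, R = Z.shape
    K = len(U_init)
    U = [_psd_clip(u.copy(), eig_floor) for u in U_init]
    pi = np.full(K, 1.0 / K)
    trace: list[float] = []
    for _ in range(n_iter):
        logp = np.empty((n, K))
        solves = []
        for k in range(K):
            T = U[k] + np.eye(R)
            L = np.linalg.cholesky(T)
            half = np.linalg.solve(L, Z.T)            # (R, n)
            quad = (half ** 2).sum(axis=0)
            logdet = 2 * np.log(np.diag(L)).sum()
            logp[:, k] = -0.5 * (R * _LOG2PI + logdet + quad) + np.log(pi[k] + 1e-300)
            solves.append(np.linalg.solve(T, np.eye(R)))
        m = logp.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logp - m).sum(axis=1))
        obj = float(lse.sum())
        if trace and obj < trace[-1] - 1e-6 * max(1.0, abs(trace[-1])):
            raise RuntimeError("ED objective decreased")
        trace.append(obj)
        resp = np.exp(logp - lse[:, None])            # (n, K)
        for k in range(K):
            Tinv = solves[k]
            A = U[k] @ Tinv                            # U (U+I)^-1
            mean_k = Z @ A.T                           # (n, R) posterior means
            cov_k = U[k] - A @ U[k]                    # common conditional cov
            w = resp[:, k]
            W = w.sum()
            if W < 1e-12:
                continue
            second = (mean_k * w[:, None]).T @ mean_k / W + cov_k
            U[k] = _psd_clip(second, eig_floor)
        pi = resp.mean(axis=0)
    return U, trace


def select_strong(lfsr: pd.DataFrame, lfsr_threshold: float = 0.1) -> pd.Index:
    """Associations with minimum lfsr across conditions strictly below threshold."""
    strong = lfsr.index[lfsr.min(axis=1) < lfsr_threshold]
    if len(strong) == 0:
        raise ValueError(
            f"no association has lfsr < {lfsr_threshold} in any condition; "
            "relax the threshold"
        )
    return strong


@dataclass
class MashModel:
    """Fitted covariance-mixture prior."""

    U: dict[str, np.ndarray]
    grid: np.ndarray                       # omega scales (variances)
    pi: pd.Series                          # weight per "null" / "U;omega" label
    conditions: list[str]
    loglik_trace: list[float] = field(default_factory=list)
    null_corr: np.ndarray | None = None    # cross-condition error correlation

    def components(self) -> list[tuple[str, np.ndarray]]:
        """Expanded (label, covariance) list, null first."""
        R = len(self.conditions)
        comps = [("null", np.zeros((R, R)))]
        for name, U in self.U.items():
            for om in self.grid:
                comps.append((f"{name};{om:.6g}", om * U))
        return comps

    def save(self, path: str | Path) -> None:
        path = Path(path)
        payload = {
            "conditions": self.conditions,
            "grid": self.grid.tolist(),
            "pi": {k: float(v) for k, v in self.pi.items()},
            "U": {k: v.tolist() for k, v in self.U.items()},
            "loglik_trace": self.loglik_trace,
            "null_corr": None if self.null_corr is None else self.null_corr.tolist(),
        }
        path.write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "MashModel":
        d = json.loads(Path(path).read_text())
        nc = d.get("null_corr")
        return cls(
            U={k: np.asarray(v) for k, v in d["U"].items()},
            grid=np.asarray(d["grid"]),
            pi=pd.Series(d["pi"]),
            conditions=d["conditions"],
            loglik_trace=d.get("loglik_trace", []),
            null_corr=None if nc is None else np.asarray(nc),
        )


def auto_grid(stats: MultiConditionStats) -> np.ndarray:
    """sqrt(2)-spaced variance grid covering [s_min/10, 2*max|b|]."""
    s_min = stats.S[stats.S < 1e5].min() if np.any(stats.S < 1e5) else stats.S.min()
    b_max = max(np.abs(stats.Bhat).max(), s_min)
    lo = s_min / 10.0
    hi = max(2.0 * b_max, 2 * lo)
    n = int(np.ceil(2 * np.log2(hi / lo))) + 1
    sigmas = lo * (np.sqrt(2.0) ** np.arange(n))
    return sigmas ** 2


def _noise_covariances(stats: MultiConditionStats, null_corr: np.ndarray | None) -> np.ndarray:
    """(n, R, R) per-association error covariance diag(s) V diag(s)."""
    n, R = stats.n, stats.R
    if null_corr is None:
        D = np.zeros((n, R, R))
        D[:, np.arange(R), np.arange(R)] = stats.S ** 2
        return D
    return stats.S[:, :, None] * null_corr[None, :, :] * stats.S[:, None, :]


def _component_logliks(
    stats: MultiConditionStats,
    comps: list[tuple[str, np.ndarray]],
    D: np.ndarray | None = None,
) -> np.ndarray:
    """(n, M) log N(bhat_i; 0, Sigma_m + D_i) via batched Cholesky."""
    n, R = stats.n, stats.R
    if D is None:
        D = _noise_covariances(stats, None)
    out = np.empty((n, len(comps)))
    for m, (_, C) in enumerate(comps):
        T = D + C[None, :, :]
        L = np.linalg.cholesky(T)
        half = np.linalg.solve(L, stats.Bhat[:, :, None])[:, :, 0]
        quad = (half ** 2).sum(axis=1)
        logdet = 2 * np.log(L[:, np.arange(R), np.arange(R)]).sum(axis=1)
        out[:, m] = -0.5 * (R * _LOG2PI + logdet + quad)
    return out


def fit_mash_weights(
    stats: MultiConditionStats,
    U: dict[str, np.ndarray],
    grid: np.ndarray | None = None,
    null_corr: np.ndarray | None = None,
    max_iter: int = 5000,
    tol: float = 1e-8,
) -> MashModel:
    """Penalized EM fit of the mixture weights pi over (U_k, omega_l) pairs
    plus a null component.

    A null-biased Dirichlet prior (pseudo-count 10 on the null) resolves the
    ridge between the null and vanishing-scale components. Convergence
    requires both a small relative objective change and stable weights; an
    objective decrease aborts (EM guarantee violated = bug).
    """
    grid = auto_grid(stats) if grid is None else np.asarray(grid, dtype=float)
    model = MashModel(U=U, grid=grid, pi=pd.Series(dtype=float),
                      conditions=stats.conditions, null_corr=null_corr)
    comps = model.components()
    L = _component_logliks(stats, comps, _noise_covariances(stats, null_corr))
    M = len(comps)
    lam = np.ones(M)
    lam[0] = 10.0                                    # null-biased prior
    pi, trace = _mixture_weight_em(L, lam, max_iter=max_iter, tol=tol)
    pi = pi / pi.sum()
    model.pi = pd.Series(pi, index=[name for name, _ in comps])
    model.loglik_trace = trace
    return model


@dataclass
class PosteriorSet:
    """Condition-wise posterior summaries for each association."""

    ids: pd.Index
    post_mean: pd.DataFrame
    post_sd: pd.DataFrame
    lfsr: pd.DataFrame


def mash_posterior(stats: MultiConditionStats, model: MashModel) -> PosteriorSet:
    """Mixture posterior mean, sd and lfsr per association and condition."""
    if model.conditions != stats.conditions:
        raise ValueError("condition mismatch between stats and model")
    n, R = stats.n, stats.R
    comps = model.components()
    pi = model.pi.to_numpy()
    Dfull = _noise_covariances(stats, model.null_corr)
    L = _component_logliks(stats, comps, Dfull)
    w = L + np.log(pi + 1e-300)
    mx = w.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.exp(w - mx).sum(axis=1))
    resp = np.exp(w - lse[:, None])                   # (n, M)

    mean_acc = np.zeros((n, R))
    second_acc = np.zeros((n, R))
    neg = np.zeros((n, R))
    pos = np.zeros((n, R))
    point = np.zeros((n, R))
    eyeidx = np.arange(R)
    for m, (_, C) in enumerate(comps):
        g = resp[:, m]
        if np.all(C == 0):
            point += g[:, None]
            continue
        if pi[m] < 1e-8:  # negligible mixture weight, skip the solves
            point += g[:, None]
            continue
        T = Dfull + C[None, :, :]
        Tinv_C = np.linalg.solve(T, np.broadcast_to(C, (n, R, R)))
        mu = np.einsum("nr,nrq->nq", stats.Bhat, Tinv_C)          # C T^-1 b
        cov_diag = C[eyeidx, eyeidx][None, :] - np.einsum(
            "rq,nqr->nr", C, Tinv_C
        )
        cov_diag = np.maximum(cov_diag, 0.0)
        sd = np.sqrt(cov_diag)
        mean_acc += g[:, None] * mu
        second_acc += g[:, None] * (cov_diag + mu ** 2)
        degen = sd < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            cdf0 = norm.cdf(0.0, loc=mu, scale=np.where(degen, 1.0, sd))
        # degenerate coordinates: all mass at mu (0 for zero-variance prior rows)
        neg += g[:, None] * np.where(degen, (mu < 0).astype(float), cdf0)
        pos += g[:, None] * np.where(degen, (mu > 0).astype(float), 1 - cdf0)
        point += g[:, None] * np.where(degen & (np.abs(mu) < 1e-12), 1.0, 0.0)
    lfsr = np.clip(np.minimum(neg + point, pos + point), 0.0, 1.0)
    post_sd = np.sqrt(np.maximum(second_acc - mean_acc ** 2, 0.0))
    cols = stats.conditions
    return PosteriorSet(
        ids=stats.ids,
        post_mean=pd.DataFrame(mean_acc, index=stats.ids, columns=cols),
        post_sd=pd.DataFrame(post_sd, index=stats.ids, columns=cols),
        lfsr=pd.DataFrame(lfsr, index=stats.ids, columns=cols),
    )


def run_mash(
    stats: MultiConditionStats,
    strong_lfsr: float = 0.1,
    n_pcs: int = 5,
    ed_iters: int = 50,
    subset_size: int = 10_000,
    seed: int = 2023,
    grid: np.ndarray | None = None,
    estimate_null_corr: bool = True,
) -> tuple[MashModel, PosteriorSet]:
    """Full mash workflow: per-condition ash, strong-set selection, canonical
    plus data-driven covariances, null error-correlation estimation, weight
    fitting on a random subset, posteriors for all associations."""
    R = stats.R
    null_corr = estimate_null_correlation(stats) if estimate_null_corr else None
    lfsr_uni = np.column_stack(
        [ash_univariate(stats.Bhat[:, r], stats.S[:, r])["lfsr"].to_numpy() for r in range(R)]
    )
    lfsr_df = pd.DataFrame(lfsr_uni, index=stats.ids, columns=stats.conditions)
    strong = select_strong(lfsr_df, strong_lfsr)
    strong_mask = stats.ids.isin(strong)
    U = canonical_covariances(R)
    Z = stats.zscores()[strong_mask]
    U.update(datadriven_covariances(Z, n_pcs=n_pcs, ed_iters=ed_iters))
    rng = np.random.default_rng(seed)
    if stats.n > subset_size:
        pick = np.sort(rng.choice(stats.n, size=subset_size, replace=False))
    else:
        pick = np.arange(stats.n)
    sub = MultiConditionStats(
        ids=stats.ids[pick], Bhat=stats.Bhat[pick], S=stats.S[pick],
        conditions=stats.conditions,
    )
    model = fit_mash_weights(sub, U, grid=grid, null_corr=null_corr)
    post = mash_posterior(stats, model)
    return model, post
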