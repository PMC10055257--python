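"""Significance calling, top-eQTL selection, sharing, and specificity classes.

An association qualifies if its lfsr is at most the primary threshold (0.05)
in at least one cell type; within qualifying associations a cell type is
called significant at the secondary threshold (0.1). Top eQTL are the
lowest-lfsr significant association per gene and cell type. Specificity uses
the two-cell-type buffer rule: significant in >= (n_types - buffer) cell
types = global, exactly one = unique, otherwise multi. Genes with several top
eQTL are pruned by clustering their centered absolute effect profiles.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import silhouette_samples

log = logging.getLogger(__name__)


def call_significance(
    lfsr: pd.DataFrame, primary: float = 0.05, secondary: float = 0.1
) -> pd.DataFrame:
    """Boolean significance mask: rows qualify iff min lfsr <= primary; within
    qualifying rows, cell types with lfsr <= secondary are significant."""
    lf = lfsr.to_numpy()
    qualifies = lf.min(axis=1) <= primary
    mask = (lf <= secondary) & qualifies[:, None]
    return pd.DataFrame(mask, index=lfsr.index, columns=lfsr.columns)


def select_top(
    posterior_beta: pd.DataFrame,
    lfsr: pd.DataFrame,
    mask: pd.DataFrame,
    tss_dist: pd.Series | None = None,
) -> pd.DataFrame:
    """Per (gene, cell type): the significant association with minimal lfsr.

    Association ids must be "gene:variant". Ties break by larger |posterior
    beta|, then lexicographic variant id. Returns a long frame with one row
    per retained (gene, cell_type).
    """
    ids = lfsr.index
    genes = pd.Series([i.split(":", 1)[0] for i in ids], index=ids)
    variants = pd.Series([i.split(":", 1)[1] for i in ids], index=ids)
    rows = []
    for ct in lfsr.columns:
        sig = mask[ct]
        if not sig.any():
            continue
        df = pd.DataFrame(
            {
                "gene": genes[sig], "variant": variants[sig],
                "lfsr": lfsr.loc[sig, ct], "beta": posterior_beta.loc[sig, ct],
            }
        )
        df["abs_beta"] = df["beta"].abs()
        df = df.sort_values(
            ["gene", "lfsr", "abs_beta", "variant"], ascending=[True, True, False, True]
        )
        top = df.groupby("gene", sort=True).head(1)
        for assoc_id, r in top.iterrows():
            rows.append(
                {
                    "assoc_id": assoc_id, "gene": r["gene"], "variant": r["variant"],
                    "cell_type": ct, "lfsr": r["lfsr"], "beta": r["beta"],
                    "tss_dist": tss_dist.get(assoc_id, np.nan) if tss_dist is not None else np.nan,
                }
            )
    return pd.DataFrame(rows)


def pairwise_sharing(
    posterior_beta: pd.DataFrame,
    mask: pd.DataFrame,
    top_ids: pd.Index,
    factor: float = 0.5,
) -> pd.DataFrame:
    """Fraction of top eQTL shared between each pair of cell types.

    A top eQTL is shared between two cell types if significant in both and the
    effect sizes have the same sign with magnitude ratio >= ``factor``. Pairs
    with no jointly significant eQTL get NaN.
    """
    cts = list(posterior_beta.columns)
    B = posterior_beta.loc[top_ids].to_numpy()
    M = mask.loc[top_ids].to_numpy()
    out = np.full((len(cts), len(cts)), np.nan)
    for a in range(len(cts)):
        out[a, a] = 1.0
        for b in range(a + 1, len(cts)):
            both = M[:, a] & M[:, b]
            if not both.any():
                log.info("sharing %s/%s: no jointly significant top eQTL", cts[a], cts[b])
                continue
            ba, bb = B[both, a], B[both, b]
            same_sign = np.sign(ba) == np.sign(bb)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.minimum(np.abs(ba), np.abs(bb)) / np.maximum(np.abs(ba), np.abs(bb))
            shared = same_sign & (ratio >= factor)
            out[a, b] = out[b, a] = shared.mean()
    return pd.DataFrame(out, index=cts, columns=cts)


def classify_specificity(mask_row: np.ndarray, n_types: int | None = None, buffer: int = 2) -> str:
    """Class label from the significant-cell-type count: 1 = unique,
    >= n_types - buffer = global, otherwise multi."""
    mask_row = np.asarray(mask_row, dtype=bool)
    n = len(mask_row) if n_types is None else n_types
    if n < 3:
        raise ValueError("need at least 3 cell types to classify")
    c = int(mask_row.sum())
    if c == 0:
        raise ValueError("no significant cell type; pre-filter before classifying")
    if c == 1:
        return "unique"
    if c >= n - buffer:
        return "global"
    return "multi"


def classify_table(mask: pd.DataFrame, buffer: int = 2) -> pd.Series:
    """Row-wise specificity labels for associations with >=1 significant type."""
    keep = mask.any(axis=1)
    return pd.Series(
        [classify_specificity(mask.loc[i].to_numpy(), buffer=buffer) for i in mask.index[keep]],
        index=mask.index[keep],
        name="class",
    )


def sign_adjust(betas: np.ndarray, significant: np.ndarray | None = None) -> np.ndarray:
    """Flip the profile so the majority sign among significant cell types is
    positive; exact ties left unchanged."""
    betas = np.asarray(betas, dtype=float)
    sig = np.ones(len(betas), dtype=bool) if significant is None else np.asarray(significant, bool)
    signs = np.sign(betas[sig])
    if (signs < 0).sum() > (signs > 0).sum():
        return -betas
    return betas.copy()


def _profile_distance(profiles: np.ndarray) -> np.ndarray:
    """Euclidean distances between centered absolute effect profiles."""
    A = np.abs(profiles)
    A = A - A.mean(axis=1, keepdims=True)
    return squareform(pdist(A, metric="euclidean"), checks=False)


def prune_top(
    top: pd.DataFrame,
    posterior_beta: pd.DataFrame,
    mask: pd.DataFrame,
    dist_threshold: float = 0.2,
    k_range: tuple[int, int] = (2, 5),
) -> pd.DataFrame:
    """Collapse a gene's near-duplicate top eQTL to distinct regulatory signals.

    Effect profiles (non-significant entries zeroed) are compared by Euclidean
    distance between centered absolute values. A single eQTL is kept as is;
    two are both kept iff their distance exceeds the threshold, else the one
    significant in more cell types wins (tie: lower mean lfsr); three or more
    are clustered (complete linkage, k chosen in ``k_range`` by mean
    silhouette, capped at m - 1) unless all pairwise distances already exceed
    the threshold, and each cluster keeps its most widely significant member.
    """
    kept_rows = []
    for gene, sub in top.groupby("gene", sort=True):
        assoc_ids = sub["assoc_id"].unique().tolist()
        m = len(assoc_ids)
        if m == 1:
            kept_rows.append((gene, assoc_ids))
            continue
        B = posterior_beta.loc[assoc_ids].to_numpy().copy()
        Mk = mask.loc[assoc_ids].to_numpy()
        B[~Mk] = 0.0
        D = _profile_distance(B)
        n_sig = Mk.sum(axis=1)
        mean_lfsr = sub.groupby("assoc_id")["lfsr"].mean().loc[assoc_ids].to_numpy()

        def representative(idx: np.ndarray) -> list[int]:
            order = sorted(idx, key=lambda i: (-n_sig[i], mean_lfsr[i], assoc_ids[i]))
            return [order[0]]

        if m == 2:
            if D[0, 1] > dist_threshold:
                winners = [0, 1]
            else:
                winners = representative(np.array([0, 1]))
        else:
            offdiag = D[np.triu_indices(m, 1)]
            if np.all(offdiag > dist_threshold):
                winners = list(range(m))
            else:
                Zl = linkage(squareform(D, checks=False), method="complete")
                best_k, best_sil = None, -np.inf
                for k in range(k_range[0], min(k_range[1], m - 1) + 1):
                    labels = fcluster(Zl, t=k, criterion="maxclust")
                    if len(np.unique(labels)) < 2:
                        continue
                    sil = float(np.mean(silhouette_samples(D, labels, metric="precomputed")))
                    if sil > best_sil + 1e-12:
                        best_k, best_sil = k, sil
                labels = fcluster(Zl, t=best_k if best_k else 2, criterion="maxclust")
                winners = []
                for lab in np.unique(labels):
                    winners += representative(np.flatnonzero(labels == lab))
        kept_rows.append((gene, [assoc_ids[i] for i in sorted(winners)]))
    keep_ids = {a for _, ids in kept_rows for a in ids}
    return top[top["assoc_id"].isin(keep_ids)].reset_index(drop=True)
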