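"""Enrichment testing with TSS-distance-matched null sets, and the Wilcoxon
differential-expression test used for interaction-eGene overlap."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


@dataclass
class EnrichmentResult:
    """Two-by-two Fisher test of a foreground set against a background set."""

    foreground_id: str
    background_id: str
    table: np.ndarray          # [[fg&bg, fg&!bg], [!fg&bg, !fg&!bg]]
    odds_ratio: float
    p: float


def fisher_enrichment(
    foreground: set, background: set, universe: set,
    foreground_id: str = "foreground", background_id: str = "background",
) -> EnrichmentResult:
    """Two-sided Fisher exact test for overlap of two sets within a universe.

    The odds ratio uses the Haldane half-count correction when a cell is zero.
    """
    if not universe:
        raise ValueError("empty universe")
    fg = foreground & universe
    bg = background & universe
    a = len(fg & bg)
    b = len(fg - bg)
    c = len(bg - fg)
    d = len(universe - fg - bg)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="two-sided")
    if min(a, b, c, d) == 0:
        orr = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
    else:
        orr = (a * d) / (b * c)
    return EnrichmentResult(foreground_id, background_id, table, float(orr), float(p))


def matched_null(
    pool: pd.Series,
    target_values: np.ndarray,
    n: int,
    seed: int,
    bw_method: str | float = "scott",
    max_passes: int = 200,
) -> pd.Index:
    """Sample ``n`` pool items whose value distribution matches the target.

    Kernel-density estimates of the target and pool distributions give each
    candidate an acceptance probability proportional to the density ratio;
    rejection sampling (seeded, deterministic) draws until ``n`` acceptances.
    Raises if the overall acceptance rate falls below 1%.
    """
    rng = np.random.default_rng(seed)
    target = np.asarray(target_values, dtype=float)
    vals = pool.to_numpy(dtype=float)
    if len(target) < 2 or len(vals) < 2:
        raise ValueError("need at least 2 target and pool values")
    kde_t = stats.gaussian_kde(target, bw_method=bw_method)
    kde_p = stats.gaussian_kde(vals, bw_method=bw_method)
    dens_t = kde_t(vals)
    dens_p = np.maximum(kde_p(vals), 1e-300)
    ratio = dens_t / dens_p
    # scale so the bulk of candidates has probability <= 1 (cap heavy tails)
    scale = np.quantile(ratio, 0.99)
    accept_p = np.minimum(ratio / max(scale, 1e-300), 1.0)
    chosen: list[int] = []
    chosen_mask = np.zeros(len(vals), dtype=bool)
    tried = 0
    for _ in range(max_passes):
        order = rng.permutation(len(vals))
        u = rng.random(len(vals))
        for i in order:
            if chosen_mask[i]:
                continue
            tried += 1
            if u[i] < accept_p[i]:
                chosen.append(i)
                chosen_mask[i] = True
                if len(chosen) == n:
                    return pool.index[chosen]
        if tried > 100 and len(chosen) / tried < 0.01:
            raise ValueError(
                f"acceptance rate {len(chosen)/tried:.3%} below 1%; enlarge the pool"
            )
    raise ValueError(f"could not accept {n} items from pool of {len(vals)}")


def wilcoxon_de(
    expr: pd.DataFrame,
    groups: pd.Series,
    adj_threshold: float = 0.1,
    exact_max_n: int = 12,
) -> pd.DataFrame:
    """Per-gene Wilcoxon rank-sum test between two groups.

    Returns AUC (probability that an observation from the second group
    exceeds one from the first, i.e. AUC -> 1 when the second group is
    upregulated), two-sided p (exact enumeration when the total sample size
    is small and tie-free, normal approximation with tie correction
    otherwise), log fold change (second minus first group mean on the
    already-log expression scale), BH-adjusted p and a DE flag at
    ``adj_threshold``. Constant genes get p = 1, AUC = 0.5. Group order
    follows first appearance in ``groups``.
    """
    labels = groups.loc[expr.index]
    uniq = pd.unique(labels)
    if len(uniq) != 2:
        raise ValueError(f"need exactly two groups, got {list(uniq)}")
    g1 = expr.index[labels == uniq[0]]
    g2 = expr.index[labels == uniq[1]]
    if min(len(g1), len(g2)) < 3:
        raise ValueError("each group needs >= 3 observations")
    rows = []
    for gene in expr.columns:
        x = expr.loc[g1, gene].to_numpy(dtype=float)
        y = expr.loc[g2, gene].to_numpy(dtype=float)
        if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
            rows.append({"gene": gene, "auc": 0.5, "p": 1.0,
                         "logFC": 0.0})
            continue
        has_ties = len(np.unique(np.concatenate([x, y]))) < len(x) + len(y)
        method = "exact" if (len(x) + len(y) <= exact_max_n and not has_ties) else "asymptotic"
        res = stats.mannwhitneyu(y, x, alternative="two-sided", method=method)
        rows.append(
            {
                "gene": gene,
                "auc": float(res.statistic) / (len(x) * len(y)),
                "p": float(res.pvalue),
                "logFC": float(y.mean() - x.mean()),
            }
        )
    out = pd.DataFrame(rows).set_index("gene")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    out["de"] = out["p_adj"] < adj_threshold
    return out


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(p, dtype=float), method="fdr_bh")[1]


def threshold_overlap(
    eqtl: pd.DataFrame,
    external: pd.DataFrame,
    p_cut: float = 1e-6,
) -> pd.DataFrame:
    """Per eQTL class: count and fraction of variants that are external hits.

    ``eqtl`` needs columns ``variant`` and ``class``; ``external`` needs
    ``variant`` and ``p``. Variant ids must already be harmonized.
    """
    hits = set(external.loc[external["p"] < p_cut, "variant"])
    shared = set(external["variant"]) & set(eqtl["variant"])
    if not shared:
        log.warning("no shared variants between eQTL set and external stats")
        return pd.DataFrame(columns=["class", "n", "n_hit", "fraction"])
    rows = []
    for cls, sub in eqtl.groupby("class", sort=True):
        vs = set(sub["variant"])
        n_hit = len(vs & hits)
        rows.append({"class": cls, "n": len(vs), "n_hit": n_hit,
                     "fraction": n_hit / len(vs) if vs else np.nan})
    return pd.DataFrame(rows)
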