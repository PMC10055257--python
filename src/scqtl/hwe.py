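"""Exact test for Hardy-Weinberg equilibrium.

Conditions on the observed allele counts and sums the exact probabilities of
heterozygote counts as or less likely than the observed one (the standard
biallelic exact test; a mid-p variant halves the probability of the observed
configuration).
"""

from __future__ import annotations

import numpy as np


def hwe_heterozygote_pmf(n_het_obs: int, n_hom_ref: int, n_hom_alt: int) -> tuple[np.ndarray, np.ndarray]:
    """Exact pmf of the heterozygote count given allele counts.

    Returns the support (het counts with the observed parity) and their
    probabilities. Computed by the usual two-sided recurrence from the mode,
    in double precision with final normalization.
    """
    n = n_het_obs + n_hom_ref + n_hom_alt
    n_rare = 2 * min(n_hom_ref, n_hom_alt) + n_het_obs  # rare allele copies
    if n == 0:
        return np.array([0]), np.array([1.0])
    # support: het counts with same parity as n_rare, 0..n_rare
    support = np.arange(n_rare % 2, n_rare + 1, 2)
    # unnormalized probabilities via recurrence:
    # P(h+2)/P(h) = (n_rare - h)(2n - n_rare - h) / ((h+2)(h+1))
    logp = np.zeros(len(support))
    for i in range(1, len(support)):
        h = support[i - 1]
        ratio = ((n_rare - h) * (2 * n - n_rare - h)) / ((h + 2.0) * (h + 1.0))
        logp[i] = logp[i - 1] + np.log(ratio)
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    return support, p


def hwe_exact_test(n_het: int, n_hom_ref: int, n_hom_alt: int, midp: bool = False) -> float:
    """Exact Hardy-Weinberg p-value for observed genotype counts.

    Parameters
    ----------
    n_het, n_hom_ref, n_hom_alt
        Genotype counts. ``midp=True`` gives the mid-p version (half weight on
        configurations exactly as likely as the observed one).
    """
    if min(n_het, n_hom_ref, n_hom_alt) < 0:
        raise ValueError("negative genotype count")
    support, p = hwe_heterozygote_pmf(n_het, n_hom_ref, n_hom_alt)
    obs = np.flatnonzero(support == n_het)
    if len(obs) == 0:  # monomorphic or impossible parity
        return 1.0
    p_obs = p[obs[0]]
    tol = 1e-12
    if midp:
        pval = p[p < p_obs * (1 - tol)].sum() + 0.5 * p[np.abs(p - p_obs) <= p_obs * tol].sum()
    else:
        pval = p[p <= p_obs * (1 + tol)].sum()
    return float(min(pval, 1.0))
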