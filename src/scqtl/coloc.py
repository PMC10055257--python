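"""Approximate-Bayes-factor colocalization of two association signals.

For each SNP a Wakefield approximate Bayes factor summarizes the evidence for
association in each trait; assuming at most one causal variant per trait the
five hypotheses (H0 no association, H1/H2 association in one trait, H3 two
distinct causal variants, H4 one shared causal variant) have posteriors
computed by summing per-SNP ABFs with prior SNP probabilities p1, p2, p12.
PP4 >= 0.6 is the conventional call for a shared causal variant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

log = logging.getLogger(__name__)

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def wakefield_log_abf(beta: np.ndarray, se: np.ndarray, prior_sd: float) -> np.ndarray:
    """log Wakefield ABF: 0.5*log(1-r) + z^2 r / 2 with r = w/(w+se^2)."""
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if np.any(~np.isfinite(beta)) or np.any(~np.isfinite(se)) or np.any(se <= 0) or prior_sd <= 0:
        raise ValueError("beta/se must be finite, se and prior_sd positive")
    r = prior_sd ** 2 / (prior_sd ** 2 + se ** 2)
    z = beta / se
    return 0.5 * np.log1p(-r) + z ** 2 * r / 2.0


@dataclass
class ColocResult:
    """Posterior hypothesis probabilities for one region pair."""

    pp0: float
    pp1: float
    pp2: float
    pp3: float
    pp4: float
    n_shared: int
    top_shared_variant: str | None
    skipped: str | None = None

    def as_dict(self) -> dict:
        return {
            "pp0": self.pp0, "pp1": self.pp1, "pp2": self.pp2,
            "pp3": self.pp3, "pp4": self.pp4, "n_shared": self.n_shared,
            "top_shared_variant": self.top_shared_variant, "skipped": self.skipped,
        }


def derive_beta_se(p: np.ndarray, maf: np.ndarray, n: np.ndarray, case_fraction: float = 0.0) -> tuple[np.ndarray, np.ndarray]:
    """Recover |beta| and se from p, MAF and N when effect sizes are missing.

    Uses se = 1/sqrt(2 maf (1-maf) n_eff) with n_eff = N for quantitative
    traits (sdY ~ 1) and N * s(1-s) scaled for case/control log-odds.
    """
    from scipy.stats import norm

    z = norm.isf(np.asarray(p, dtype=float) / 2.0)
    n_eff = np.asarray(n, dtype=float)
    if case_fraction > 0:
        n_eff = n_eff * case_fraction * (1 - case_fraction)
    se = 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n_eff)
    return z * se, se


def harmonize(stats1: pd.DataFrame, stats2: pd.DataFrame) -> pd.DataFrame:
    """Intersect two summary tables on chrom:pos:ref:alt, flipping alleles and
    strand where needed; unresolvable and ambiguous (A/T, C/G) variants are
    dropped with a log message. Returns merged frame with beta1/se1/beta2/se2.
    """

    def key(df):
        return (
            df["chrom"].astype(str) + ":" + df["pos"].astype(str) + ":"
            + df["ref"].str.upper() + ":" + df["alt"].str.upper()
        )

    s1 = stats1.copy()
    s2 = stats2.copy()
    s1["_key"] = key(s1)
    ambiguous = s2.apply(lambda r: _COMPLEMENT.get(r["ref"].upper()) == r["alt"].upper(), axis=1)
    if ambiguous.any():
        log.info("dropping %d strand-ambiguous variants", int(ambiguous.sum()))
        s2 = s2[~ambiguous]
    rows = []
    lookup = s1.set_index("_key")
    for _, r in s2.iterrows():
        ref, alt = r["ref"].upper(), r["alt"].upper()
        tried = [
            (ref, alt, 1.0),
            (alt, ref, -1.0),
            (_COMPLEMENT.get(ref, "N"), _COMPLEMENT.get(alt, "N"), 1.0),
            (_COMPLEMENT.get(alt, "N"), _COMPLEMENT.get(ref, "N"), -1.0),
        ]
        for a, b, flip in tried:
            k = f"{r['chrom']}:{r['pos']}:{a}:{b}"
            if k in lookup.index:
                m = lookup.loc[k]
                rows.append(
                    {
                        "variant": m.get("variant", k), "chrom": r["chrom"], "pos": r["pos"],
                        "beta1": m["beta"], "se1": m["se"],
                        "beta2": flip * r["beta"], "se2": r["se"],
                        "maf1": m.get("maf", np.nan), "maf2": r.get("maf", np.nan),
                    }
                )
                break
    return pd.DataFrame(rows)


def coloc_abf(
    merged: pd.DataFrame,
    p1: float = 1e-4,
    p2: float = 1e-4,
    p12: float = 1e-5,
    prior_sd1: float = 0.15,
    prior_sd2: float = 0.2,
    min_shared: int = 100,
) -> ColocResult:
    """Colocalization posteriors from harmonized per-SNP statistics.

    ``merged`` needs columns beta1/se1/beta2/se2 (one row per shared variant);
    rows whose MAF columns show a non-variable SNP (0 or 1) are excluded from
    the shared-variant count. Entries with fewer than ``min_shared`` variable
    SNPs are skipped.
    """
    df = merged
    variable = np.ones(len(df), dtype=bool)
    for c in ("maf1", "maf2"):
        if c in df.columns and df[c].notna().all():
            variable &= (df[c] > 0) & (df[c] < 1)
    df = df[variable]
    n_shared = len(df)
    if n_shared < min_shared:
        return ColocResult(np.nan, np.nan, np.nan, np.nan, np.nan, n_shared, None,
                           skipped=f"only {n_shared} shared variable SNPs < {min_shared}")
    if n_shared == 0:
        raise ValueError("zero overlapping variants")
    l1 = wakefield_log_abf(df["beta1"].to_numpy(), df["se1"].to_numpy(), prior_sd1)
    l2 = wakefield_log_abf(df["beta2"].to_numpy(), df["se2"].to_numpy(), prior_sd2)
    lsum = l1 + l2
    lh0 = 0.0
    lh1 = np.log(p1) + logsumexp(l1)
    lh2 = np.log(p2) + logsumexp(l2)
    # H3: sum over ordered pairs i != j of ABF1_i * ABF2_j
    both = logsumexp(l1) + logsumexp(l2)
    same = logsumexp(lsum)
    # stable log(exp(both) - exp(same))
    if both <= same:
        lh3 = -np.inf
    else:
        lh3 = np.log(p1) + np.log(p2) + both + np.log1p(-np.exp(same - both))
    lh4 = np.log(p12) + same
    lall = np.array([lh0, lh1, lh2, lh3, lh4])
    pp = np.exp(lall - logsumexp(lall))
    top_idx = int(np.argmax(lsum))
    top = str(df["variant"].iloc[top_idx]) if "variant" in df.columns else None
    return ColocResult(*pp, n_shared=n_shared, top_shared_variant=top)
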