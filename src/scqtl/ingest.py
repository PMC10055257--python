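"""Input parsing, QC filters and pseudo-bulk aggregation.

Reads donor genotypes (VCF or dosage TSV) and cell-level counts
(MatrixMarket + TSV metadata), applies the standard single-cell eQTL QC:
MAF/HWE/LD variant filters, mitochondrial-fraction cell QC, expression-based
gene filters, scran-style normalization, and per-cell-type mean aggregation
to donor-level pseudo-bulk with minimum cell and donor thresholds.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .containers import GenotypeMatrix, PseudobulkMatrix, PseudobulkSet

log = logging.getLogger(__name__)


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    """Read a VCF (``.vcf``/``.vcf.gz``) or donor x variant dosage TSV.

    Multi-allelic records are skipped with a warning; missing genotypes are
    imputed to the per-variant mean dosage.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".tsv", ".txt") or path.name.endswith(".tsv.gz"):
        return _read_dosage_tsv(path)
    return _read_vcf(path)


def _read_vcf(path: Path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    donors = np.array(vcf.samples, dtype=object)
    if len(donors) == 0:
        raise ValueError("VCF contains zero donors")
    rows, cols = [], []
    n_multi = n_imputed = 0
    for rec in vcf:
        if len(rec.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 = alt dosage, 3 = missing
        g = rec.gt_types.astype(float)
        miss = g == 3
        if miss.any():
            known = g[~miss]
            g[miss] = known.mean() if len(known) else 0.0
            n_imputed += int(miss.sum())
        vid = rec.ID if rec.ID not in (None, ".") else f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        rows.append({"variant_id": vid, "chrom": rec.CHROM, "pos": rec.POS,
                     "ref": rec.REF, "alt": rec.ALT[0]})
        cols.append(g)
    if n_multi:
        log.warning("skipped %d multi-allelic records", n_multi)
    if n_imputed:
        log.warning("mean-imputed %d missing genotypes", n_imputed)
    if not rows:
        raise ValueError(f"no biallelic records in {path}")
    return GenotypeMatrix(donors, pd.DataFrame(rows), np.column_stack(cols))


def _read_dosage_tsv(path: Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.empty:
        raise ValueError(f"empty dosage table {path}")
    variants = pd.DataFrame({"variant_id": df.columns})
    parts = variants["variant_id"].str.split(":", expand=True)
    if parts.shape[1] >= 4:
        variants[["chrom", "pos", "ref", "alt"]] = parts.iloc[:, :4]
        variants["pos"] = variants["pos"].astype(int)
    else:
        variants["chrom"] = "NA"
        variants["pos"] = np.arange(1, len(variants) + 1)
        variants["ref"] = "N"
        variants["alt"] = "N"
    dos = df.to_numpy(dtype=float)
    col_mean = np.nanmean(dos, axis=0)
    nan_mask = np.isnan(dos)
    if nan_mask.any():
        log.warning("mean-imputed %d missing dosages", int(nan_mask.sum()))
        dos[nan_mask] = np.take(col_mean, np.nonzero(nan_mask)[1])
    return GenotypeMatrix(np.array(df.index, dtype=object), variants, dos)


def ld_prune(dosages: np.ndarray, window: int = 250, step: int = 50, r2_max: float = 0.9) -> np.ndarray:
    """Greedy sliding-window LD pruning; returns a boolean keep mask.

    Windows span ``window`` variants and advance by ``step``; within a window
    the later variant of any pair with r^2 > ``r2_max`` is removed (among
    still-kept variants), matching the variant-count pruning dialect.
    """
    m = dosages.shape[1]
    keep = np.ones(m, dtype=bool)
    X = dosages - dosages.mean(axis=0)
    sd = X.std(axis=0)
    start = 0
    while True:
        end = min(start + window, m)
        idx = np.arange(start, end)
        live = idx[keep[idx] & (sd[idx] > 0)]
        if len(live) > 1:
            Xw = X[:, live] / sd[live]
            R = (Xw.T @ Xw) / Xw.shape[0]
            r2 = R ** 2
            for a in range(len(live)):
                if not keep[live[a]]:
                    continue
                for b in range(a + 1, len(live)):
                    if keep[live[b]] and r2[a, b] > r2_max:
                        keep[live[b]] = False
        # monomorphic variants cannot be tested; keep them for MAF filter to drop
        if end >= m:
            break
        start += step
    return keep


def filter_variants(
    G: GenotypeMatrix,
    maf_min: float = 0.05,
    hwe_p_min: float = 1e-6,
    ld_window: int = 250,
    ld_step: int = 50,
    ld_r2: float = 0.9,
) -> GenotypeMatrix:
    """MAF > ``maf_min``, HWE exact p > ``hwe_p_min`` (both strict), then LD pruning."""
    if G.n_variants == 0:
        raise ValueError("empty genotype matrix")
    maf = G.maf()
    hwe = G.hwe_p()
    mask = (maf > maf_min) & (hwe > hwe_p_min)
    kept = G.subset_variants(mask)
    if kept.n_variants == 0:
        warnings.warn("no variants pass MAF/HWE filters")
        return kept
    keep = ld_prune(kept.dosages, ld_window, ld_step, ld_r2)
    out = kept.subset_variants(keep)
    log.info("variant filter: %d -> %d (MAF/HWE) -> %d (LD prune)",
             G.n_variants, kept.n_variants, out.n_variants)
    return out


def read_cell_counts(mtx: str | Path, cells_tsv: str | Path, genes_tsv: str | Path) -> AnnData:
    """Assemble an AnnData from MatrixMarket counts and TSV metadata."""
    X = sp.csr_matrix(scipy.io.mmread(str(mtx)))
    cells = pd.read_csv(cells_tsv, sep="\t").set_index("cell_id")
    genes = pd.read_csv(genes_tsv, sep="\t").set_index("gene_id")
    if X.shape != (len(cells), len(genes)):
        raise ValueError(
            f"matrix shape {X.shape} does not match {len(cells)} cells x {len(genes)} genes"
        )
    return AnnData(X=X, obs=cells, var=genes)


def qc_cells(adata: AnnData, mito_max: float = 0.20) -> AnnData:
    """Drop cells with mitochondrial read fraction strictly above ``mito_max``."""
    if "mito_frac" not in adata.obs.columns:
        raise ValueError("cell metadata lacks 'mito_frac'")
    keep = adata.obs["mito_frac"].to_numpy() <= mito_max
    n_drop = int((~keep).sum())
    if n_drop:
        log.info("cell QC: removed %d/%d cells with mito_frac > %.2f", n_drop, adata.n_obs, mito_max)
    return adata[keep].copy()


def filter_genes(
    adata: AnnData,
    min_cell_frac: float = 0.10,
    min_mean_count: float = 0.1,
    exclude_lists: list[str | Path] | None = None,
) -> pd.Index:
    """Genes expressed in >= ``min_cell_frac`` of all cells, mean count >=
    ``min_mean_count``, and not on any exclusion list (e.g. mitochondrial or
    ribosomal-protein gene symbols, one per line)."""
    X = adata.X
    n = adata.n_obs
    if n == 0:
        return pd.Index([])
    expressed = np.asarray((X > 0).sum(axis=0)).ravel() / n
    mean_count = np.asarray(X.sum(axis=0)).ravel() / n
    keep = (expressed >= min_cell_frac) & (mean_count >= min_mean_count)
    excluded: set[str] = set()
    for path in exclude_lists or []:
        try:
            df = pd.read_csv(path, sep="\t", header=None)
        except pd.errors.EmptyDataError:
            continue  # empty exclusion list is valid
        if df.shape[1] != 1:
            raise ValueError(f"exclusion list {path} must have a single column")
        excluded |= set(df.iloc[:, 0].astype(str))
    on_list = adata.var_names.isin(excluded)
    return adata.var_names[keep & ~on_list]


def _deconvolve_size_factors(counts: sp.spmatrix, lib: np.ndarray, rng_sizes=(21, 26, 31, 36, 41)) -> np.ndarray:
    """Pool-and-deconvolve size factors over one pool group (>=100 cells).

    Cells are arranged on a ring ordered by library size; sliding pools of
    several sizes are summed, each pool's factor is measured against the
    average pseudo-cell, and per-cell factors are recovered by least squares.
    """
    n = lib.shape[0]
    order = np.argsort(lib)
    # interleave to balance pools: smallest, largest, second smallest, ...
    ring = np.empty(n, dtype=int)
    ring[0::2] = order[: (n + 1) // 2]
    ring[1::2] = order[(n + 1) // 2:][::-1]
    C = np.asarray(counts.todense(), dtype=float)[ring]
    ref = C.mean(axis=0)
    ref_pos = ref > 0
    rows, cols, vals, b = [], [], [], []
    eq = 0
    for size in rng_sizes:
        if size > n:
            continue
        for start in range(0, n, max(1, n // 50)):
            pool = (np.arange(start, start + size)) % n
            pooled = C[pool].sum(axis=0)
            ratio = np.median(pooled[ref_pos] / ref[ref_pos])
            for c in pool:
                rows.append(eq)
                cols.append(c)
                vals.append(1.0)
            b.append(ratio)
            eq += 1
    # anchor: sum of factors equals sum of library-size factors
    lib_sf = lib / np.exp(np.mean(np.log(np.maximum(lib, 1))))
    rows += [eq] * n
    cols += list(range(n))
    vals += [1.0] * n
    b.append(lib_sf.sum())
    A = sp.csr_matrix((vals, (rows, cols)), shape=(eq + 1, n))
    sf_ring = sp.linalg.lsqr(A, np.array(b))[0]
    sf_ring = np.maximum(sf_ring, 1e-8)
    sf = np.empty(n)
    sf[ring] = sf_ring
    return sf


def normalize_log(adata: AnnData, pool_by: str | None = "donor", min_pool_cells: int = 100) -> AnnData:
    """Size-factor normalize and log2 transform counts.

    Per-cell library-size factors (library size over its geometric mean) are
    refined by pool-and-deconvolution within ``pool_by`` groups that have at
    least ``min_pool_cells`` cells; factors are rescaled to mean 1 and values
    are ``log2(count / sf + 1)``. Cells with zero library size are dropped.
    """
    X = sp.csr_matrix(adata.X, dtype=float)
    lib = np.asarray(X.sum(axis=1)).ravel()
    nz = lib > 0
    if not nz.all():
        warnings.warn(f"dropping {int((~nz).sum())} cells with zero library size")
        adata = adata[nz].copy()
        X = sp.csr_matrix(adata.X, dtype=float)
        lib = np.asarray(X.sum(axis=1)).ravel()
    sf = lib / np.exp(np.mean(np.log(lib)))
    if pool_by is not None and pool_by in adata.obs.columns:
        for _, idx in adata.obs.groupby(pool_by, observed=True).indices.items():
            if len(idx) >= min_pool_cells:
                sf[idx] = _deconvolve_size_factors(X[idx], lib[idx])
    sf = sf / sf.mean()
    norm = X.multiply(1.0 / sf[:, None]).tocsr()
    norm.data = np.log2(norm.data + 1.0)
    out = adata.copy()
    out.layers["lognorm"] = norm
    out.obs["size_factor"] = sf
    return out


def pseudobulk_aggregate(
    adata: AnnData,
    min_cells: int = 5,
    min_donors: int = 40,
    layer: str = "lognorm",
) -> PseudobulkSet:
    """Mean-aggregate normalized expression to donor level per cell type.

    Donor/cell-type combinations with fewer than ``min_cells`` cells are
    excluded; cell types with fewer than ``min_donors`` qualifying donors are
    dropped entirely.
    """
    for col in ("donor", "cell_type", "disease"):
        if col not in adata.obs.columns:
            raise ValueError(f"cell metadata lacks '{col}'")
    M = adata.layers[layer] if layer in adata.layers else adata.X
    M = sp.csr_matrix(M)
    result = {}
    report = {}
    for ct, idx in sorted(adata.obs.groupby("cell_type", observed=True).indices.items()):
        obs_ct = adata.obs.iloc[idx]
        counts = obs_ct.groupby("donor", observed=True).size()
        qualifying = counts[counts >= min_cells]
        report[ct] = len(qualifying)
        if len(qualifying) < min_donors:
            log.info("cell type %s dropped: %d qualifying donors < %d", ct, len(qualifying), min_donors)
            continue
        donors = sorted(qualifying.index)
        rows = []
        disease = []
        for d in donors:
            didx = idx[(obs_ct["donor"] == d).to_numpy()]
            rows.append(np.asarray(M[didx].mean(axis=0)).ravel())
            disease.append(obs_ct.loc[obs_ct["donor"] == d, "disease"].iloc[0])
        expr = pd.DataFrame(np.vstack(rows), index=pd.Index(donors, name="donor"),
                            columns=adata.var_names)
        result[ct] = PseudobulkMatrix(
            cell_type=ct,
            expr=expr,
            n_cells=pd.Series(qualifying.loc[donors].to_numpy(), index=expr.index, name="n_cells"),
            disease=pd.Series(disease, index=expr.index, name="disease"),
        )
    if not result:
        raise ValueError(f"no cell type passes the donor threshold; qualifying donors: {report}")
    return PseudobulkSet(result)
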