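"""Synthetic cohort generator with planted cis-eQTL structure.

Emulates a case/control single-cell eQTL study: donor genotypes with
minor-allele-frequency, Hardy-Weinberg and linkage-disequilibrium structure,
family-based kinship, per-cell negative-binomial counts driven by planted
additive and genotype-by-disease effects, and GWAS summary statistics for
colocalization tests. Every output is a deterministic function of the seed,
and the planted truth travels with the fixtures so downstream accuracy can be
scored without re-deriving it.

Counts for cell *i* of donor *d* (disease status ``x_d``, dosage ``g_d`` at a
gene's causal variant) follow

    count ~ NB(mean = 2 ** (b_g + beta_c * g_d + beta_dis * x_d
                            + beta_gd * g_d * x_d + a_d),  dispersion alpha)

with a donor random effect ``a ~ MVN(0, sigma_a^2 K)`` on the log2 scale, so
planted effect sizes are in log2-expression units per alt allele and are
directly comparable to pseudo-bulk regression slopes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from anndata import AnnData

from .containers import GenotypeMatrix, KinshipMatrix

PATTERNS = ("global", "multi", "unique", "sign_flip", "interaction_only")


@dataclass
class CellTypeSpec:
    """Sampling parameters for one cell type."""

    name: str
    mean_cells: float = 30.0       # Poisson mean cells per donor
    donor_dropout: float = 0.0     # probability a donor contributes no cells


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic cohort.

    Defaults give a desk-scale version of a case/control lung cohort:
    100 donors (58% diseased), six cell types of unequal abundance, 20 cis
    SNPs per gene in LD blocks of five.
    """

    seed: int
    n_donors: int = 100
    frac_diseased: float = 0.58
    cell_types: list[CellTypeSpec] = field(
        default_factory=lambda: [
            CellTypeSpec("AT2", 60.0),
            CellTypeSpec("AT1", 30.0),
            CellTypeSpec("Ciliated", 30.0),
            CellTypeSpec("Macrophage", 50.0, donor_dropout=0.05),
            CellTypeSpec("Tcell", 25.0, donor_dropout=0.05),
            CellTypeSpec("Fibroblast", 20.0, donor_dropout=0.10),
        ]
    )
    n_genes: int = 50
    snps_per_gene: int = 20
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_block_size: int = 5
    ld_corr: float = 0.8
    n_families: int = 0
    family_size: int = 2
    relatedness: float = 0.5
    nb_dispersion: float = 0.3
    baseline_log2: tuple[float, float] = (4.0, 6.0)
    donor_re_sd: float = 0.2
    mito_beta: tuple[float, float] = (2.0, 25.0)
    gene_spacing: int = 3_000_000
    gene_length: int = 10_000
    cis_spread: int = 200_000

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("n_donors", "n_genes", "snps_per_gene", "ld_block_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie inside (0, 0.5]")
        if not (0.0 <= self.frac_diseased <= 1.0):
            raise ValueError("frac_diseased must be in [0, 1]")
        if isinstance(self.cell_types, dict):
            self.cell_types = [CellTypeSpec(k, **v) for k, v in self.cell_types.items()]

    @property
    def cell_type_names(self) -> list[str]:
        return [ct.name for ct in self.cell_types]


@dataclass
class EffectDesign:
    """Planted eQTL truth: per gene, a causal variant and per-cell-type effects.

    ``beta`` (additive), ``beta_gd`` (genotype x disease interaction) and
    ``beta_disease`` (disease main effect) are gene x cell-type frames in
    log2-expression units. ``eqtls`` maps genes to their causal variant and
    pattern label.
    """

    eqtls: pd.DataFrame            # gene_id, variant_id, pattern
    beta: pd.DataFrame             # gene x cell type additive effects
    beta_gd: pd.DataFrame          # gene x cell type interaction effects
    beta_disease: pd.DataFrame     # gene x cell type disease main effects

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for _, row in self.eqtls.iterrows():
            g, pat = row["gene_id"], row["pattern"]
            if pat not in PATTERNS:
                raise ValueError(f"unknown pattern {pat!r}")
            b = self.beta.loc[g].to_numpy()
            bgd = self.beta_gd.loc[g].to_numpy()
            nz = np.flatnonzero(b != 0)
            if pat == "unique" and len(nz) != 1:
                raise ValueError(f"{g}: unique pattern needs exactly one nonzero beta")
            if pat == "global" and len(nz) != len(b):
                raise ValueError(f"{g}: global pattern needs all betas nonzero")
            if pat == "sign_flip" and not ((b > 0).any() and (b < 0).any()):
                raise ValueError(f"{g}: sign_flip pattern needs both signs")
            if pat == "interaction_only" and (np.any(b != 0) or not np.any(bgd != 0)):
                raise ValueError(f"{g}: interaction_only needs beta=0 and beta_gd!=0")

    def causal_variant(self, gene_id: str) -> str:
        hit = self.eqtls.loc[self.eqtls["gene_id"] == gene_id, "variant_id"]
        if hit.empty:
            raise KeyError(f"no planted eQTL for gene {gene_id}")
        return str(hit.iloc[0])

    def to_frame(self) -> pd.DataFrame:
        """Long-format truth table (one row per gene x cell type)."""
        rows = []
        for _, r in self.eqtls.iterrows():
            g = r["gene_id"]
            for ct in self.beta.columns:
                rows.append(
                    {
                        "gene_id": g,
                        "variant_id": r["variant_id"],
                        "pattern": r["pattern"],
                        "cell_type": ct,
                        "beta": self.beta.loc[g, ct],
                        "beta_gd": self.beta_gd.loc[g, ct],
                        "beta_disease": self.beta_disease.loc[g, ct],
                    }
                )
        return pd.DataFrame(rows)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EffectDesign":
        eqtls = df[["gene_id", "variant_id", "pattern"]].drop_duplicates().reset_index(drop=True)
        beta = df.pivot(index="gene_id", columns="cell_type", values="beta")
        beta_gd = df.pivot(index="gene_id", columns="cell_type", values="beta_gd")
        beta_dis = df.pivot(index="gene_id", columns="cell_type", values="beta_disease")
        order = eqtls["gene_id"].to_numpy()
        return cls(eqtls, beta.loc[order], beta_gd.loc[order], beta_dis.loc[order])


def _empty_design(genes: list[str], cell_types: list[str]) -> EffectDesign:
    z = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=cell_types)
    return EffectDesign(
        eqtls=pd.DataFrame(columns=["gene_id", "variant_id", "pattern"]),
        beta=z.copy(), beta_gd=z.copy(), beta_disease=z.copy(),
    )


def simulate_genotypes(config: SimConfig) -> tuple[GenotypeMatrix, KinshipMatrix]:
    """Simulate donor genotypes and the expected kinship matrix.

    Haplotypes are built by a copy-with-refresh process: within an LD block
    (constant target MAF), each successive allele copies the previous one with
    probability ``ld_corr``, giving adjacent-dosage correlation ~ld_corr and
    r^2 ~ld_corr^2. Donors in a family copy whole haplotypes from the family
    founder with probability ``relatedness``, so the expected kinship is
    block-diagonal with that off-diagonal value.
    """
    rng = np.random.default_rng(config.seed)
    n, m_per = config.n_donors, config.snps_per_gene
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    donors = np.array([f"D{i:03d}" for i in range(n)], dtype=object)

    # family layout: first n_families*family_size donors grouped
    founder_of = np.arange(n)
    K = np.eye(n)
    if config.n_families > 0 and config.family_size > 1:
        idx = 0
        for _ in range(config.n_families):
            members = np.arange(idx, min(idx + config.family_size, n))
            if len(members) > 1:
                founder_of[members] = members[0]
                for a in members:
                    for b in members:
                        if a != b:
                            K[a, b] = config.relatedness
            idx += config.family_size
            if idx >= n:
                break

    var_rows = []
    dosage_cols = []
    for gi, gene in enumerate(genes):
        tss = gi * config.gene_spacing + 1_000_000
        positions = np.sort(
            rng.choice(np.arange(tss - config.cis_spread, tss + config.cis_spread), m_per, replace=False)
        )
        n_blocks = int(np.ceil(m_per / config.ld_block_size))
        block_mafs = rng.uniform(*config.maf_range, size=n_blocks)
        # two haplotypes per donor; founders simulated, relatives copy
        haps = np.zeros((n, 2, m_per), dtype=np.int8)
        founders = np.unique(founder_of)
        for j in range(m_per):
            block = j // config.ld_block_size
            maf = block_mafs[block]
            fresh = (rng.random((n, 2)) < maf).astype(np.int8)
            if j % config.ld_block_size == 0:
                haps[:, :, j] = fresh
            else:
                copy = rng.random((n, 2)) < config.ld_corr
                haps[:, :, j] = np.where(copy, haps[:, :, j - 1], fresh)
        # family copying: whole haplotypes from founder, one Bernoulli per (donor, hap)
        share = rng.random((n, 2)) < config.relatedness
        for d in range(n):
            f = founder_of[d]
            if f != d:
                for h in range(2):
                    if share[d, h]:
                        haps[d, h, :] = haps[f, h, :]
        dosage_cols.append(haps.sum(axis=1).astype(float))
        for j, pos in enumerate(positions):
            var_rows.append(
                {
                    "variant_id": f"{gene}_snp{j:03d}",
                    "chrom": "1",
                    "pos": int(pos),
                    "ref": "A",
                    "alt": "G",
                    "gene_block": gene,
                }
            )
    dosages = np.concatenate(dosage_cols, axis=1)
    variants = pd.DataFrame(var_rows)
    return GenotypeMatrix(donors, variants, dosages), KinshipMatrix(donors, K)


def gene_annotation(config: SimConfig) -> pd.DataFrame:
    """Gene annotation table matching :func:`simulate_genotypes` coordinates."""
    rows = []
    for gi in range(config.n_genes):
        tss = gi * config.gene_spacing + 1_000_000
        strand = "+" if gi % 2 == 0 else "-"
        if strand == "+":
            start, end = tss, tss + config.gene_length
        else:
            start, end = tss - config.gene_length, tss
        rows.append(
            {"gene_id": f"G{gi:04d}", "chrom": "1", "tss": tss, "strand": strand,
             "start": start, "end": end}
        )
    return pd.DataFrame(rows)


def random_design(
    genotypes: GenotypeMatrix,
    config: SimConfig,
    pattern_counts: dict[str, int],
    effect_size: float = 1.0,
    interaction_size: float = 1.0,
    n_multi: int = 3,
    seed: int | None = None,
) -> EffectDesign:
    """Assign planted patterns to the first genes, one causal cis SNP each.

    ``multi`` plants the effect in ``n_multi`` cell types; ``sign_flip``
    plants it in all cell types with the last two flipped in sign. The causal
    variant is the cis SNP whose MAF is closest to 0.3 (well-powered,
    deterministic).
    """
    rng = np.random.default_rng(config.seed + 17 if seed is None else seed)
    cell_types = config.cell_type_names
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    design = _empty_design(genes, cell_types)
    maf = genotypes.maf()
    rows = []
    gi = 0
    for pattern, count in pattern_counts.items():
        if pattern not in PATTERNS:
            raise ValueError(f"unknown pattern {pattern!r}")
        for _ in range(count):
            if gi >= len(genes):
                raise ValueError("more planted effects than genes")
            gene = genes[gi]
            in_gene = genotypes.variants["gene_block"] == gene
            cand = np.flatnonzero(in_gene)
            causal = cand[np.argmin(np.abs(maf[cand] - 0.3))]
            vid = genotypes.variants["variant_id"].iloc[causal]
            b = np.zeros(len(cell_types))
            bgd = np.zeros(len(cell_types))
            sign = rng.choice([-1.0, 1.0])
            if pattern == "global":
                b[:] = sign * effect_size
            elif pattern == "multi":
                which = rng.choice(len(cell_types), size=min(n_multi, len(cell_types)), replace=False)
                b[which] = sign * effect_size
            elif pattern == "unique":
                b[rng.integers(len(cell_types))] = sign * effect_size
            elif pattern == "sign_flip":
                b[:] = sign * effect_size
                b[-2:] *= -1.0
            elif pattern == "interaction_only":
                bgd[:] = sign * interaction_size
            design.beta.loc[gene] = b
            design.beta_gd.loc[gene] = bgd
            rows.append({"gene_id": gene, "variant_id": vid, "pattern": pattern})
            gi += 1
    design.eqtls = pd.DataFrame(rows, columns=["gene_id", "variant_id", "pattern"])
    design.validate()
    return design


def simulate_cells(
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    design: EffectDesign,
    config: SimConfig,
) -> AnnData:
    """Simulate the cell x gene count matrix with metadata.

    Returns an :class:`AnnData` with sparse integer counts, per-cell ``obs``
    (donor, cell_type, disease, mito_frac) and gene annotation in ``var``.
    """
    rng = np.random.default_rng(config.seed + 1)
    donors = genotypes.donors
    n = len(donors)
    genes = [f"G{i:04d}" for i in range(config.n_genes)]
    annot = gene_annotation(config).set_index("gene_id")
    if not set(design.beta.index) <= set(genes):
        raise ValueError("design references unknown genes")
    known = set(genotypes.variants["variant_id"])
    if not set(design.eqtls["variant_id"]) <= known:
        raise ValueError("design references unknown variants")

    n_dis = int(round(config.frac_diseased * n))
    disease = np.array(["control"] * n, dtype=object)
    disease[rng.choice(n, size=n_dis, replace=False)] = "ILD"
    x_dis = (disease == "ILD").astype(float)

    baselines = rng.uniform(*config.baseline_log2, size=config.n_genes)
    # donor random effects per gene: MVN(0, sigma^2 K), shared across cell types
    L = np.linalg.cholesky(kinship.values + 1e-10 * np.eye(n))
    re = config.donor_re_sd * (L @ rng.standard_normal((n, config.n_genes)))

    # per-donor log2 mean per gene per cell type
    dose = np.zeros((n, config.n_genes))
    for _, r in design.eqtls.iterrows():
        gi = genes.index(r["gene_id"])
        vj = genotypes.variants.index[genotypes.variants["variant_id"] == r["variant_id"]][0]
        dose[:, gi] = genotypes.dosages[:, vj]

    obs_rows = []
    count_blocks = []
    alpha = config.nb_dispersion
    for ct in config.cell_types:
        b_c = design.beta[ct.name].reindex(genes).fillna(0.0).to_numpy()
        b_gd = design.beta_gd[ct.name].reindex(genes).fillna(0.0).to_numpy()
        b_d = design.beta_disease[ct.name].reindex(genes).fillna(0.0).to_numpy()
        log2mu = (
            baselines[None, :]
            + dose * b_c[None, :]
            + x_dis[:, None] * b_d[None, :]
            + dose * x_dis[:, None] * b_gd[None, :]
            + re
        )
        mu = np.exp2(log2mu)
        n_cells = rng.poisson(ct.mean_cells, size=n)
        dropped = rng.random(n) < ct.donor_dropout
        n_cells[dropped] = 0
        for d in range(n):
            k = int(n_cells[d])
            if k == 0:
                continue
            m = np.broadcast_to(mu[d], (k, config.n_genes))
            if alpha > 0:
                lam = rng.gamma(1.0 / alpha, alpha * m)
            else:
                lam = m
            counts = rng.poisson(lam)
            count_blocks.append(sp.csr_matrix(counts))
            mito = rng.beta(*config.mito_beta, size=k)
            for c in range(k):
                obs_rows.append(
                    {
                        "cell_id": f"{donors[d]}_{ct.name}_{c:04d}",
                        "donor": donors[d],
                        "cell_type": ct.name,
                        "disease": disease[d],
                        "mito_frac": mito[c],
                    }
                )
    if count_blocks:
        X = sp.vstack(count_blocks).tocsr()
    else:
        X = sp.csr_matrix((0, config.n_genes), dtype=np.int64)
    obs = pd.DataFrame(obs_rows).set_index("cell_id") if obs_rows else pd.DataFrame(
        columns=["donor", "cell_type", "disease", "mito_frac"]
    )
    var = annot.loc[genes].copy()
    adata = AnnData(X=X, obs=obs, var=var)
    adata.uns["disease_by_donor"] = dict(zip(donors.tolist(), disease.tolist()))
    return adata


def simulate_gwas_stats(
    genotypes: GenotypeMatrix,
    causal_variant: str,
    n_gwas: int = 500,
    h2_snp: float = 0.05,
    mode: str = "shared",
    seed: int = 0,
) -> pd.DataFrame:
    """Marginal GWAS summary statistics for a trait driven through the panel's LD.

    A GWAS cohort of ``n_gwas`` individuals is drawn by resampling donor
    genotype rows (preserving LD exactly); the quantitative trait loads on the
    chosen causal variant with per-SNP heritability ``h2_snp``. ``shared``
    uses the given variant, ``distinct`` the cis variant least correlated with
    it, ``null`` no genetic signal.
    """
    if mode not in ("shared", "distinct", "null"):
        raise ValueError(f"unknown mode {mode!r}")
    vids = genotypes.variants["variant_id"].to_numpy()
    hit = np.flatnonzero(vids == causal_variant)
    if len(hit) == 0:
        raise KeyError(f"variant {causal_variant} not in panel")
    ci = hit[0]
    rng = np.random.default_rng(seed)
    rows = rng.integers(0, genotypes.n_donors, size=n_gwas)
    G = genotypes.dosages[rows]
    Gc = G - G.mean(axis=0)
    sd = Gc.std(axis=0)
    if mode == "distinct":
        with np.errstate(invalid="ignore", divide="ignore"):
            r = (Gc[:, [ci]] * Gc).mean(axis=0) / (sd[ci] * sd)
        r = np.nan_to_num(r, nan=1.0)
        ci = int(np.argmin(np.abs(r)))
    y = rng.standard_normal(n_gwas)
    if mode != "null" and sd[ci] > 0:
        g_std = Gc[:, ci] / sd[ci]
        y = np.sqrt(h2_snp) * g_std + np.sqrt(1.0 - h2_snp) * rng.standard_normal(n_gwas)
    # vectorized per-SNP simple regression
    yc = y - y.mean()
    sxx = (Gc ** 2).sum(axis=0)
    sxx_safe = np.where(sxx > 0, sxx, 1.0)
    beta = (Gc * yc[:, None]).sum(axis=0) / sxx_safe
    resid_ss = (yc ** 2).sum() - beta ** 2 * sxx_safe
    dof = n_gwas - 2
    se = np.sqrt(np.maximum(resid_ss, 1e-300) / dof / sxx_safe)
    beta = np.where(sxx > 0, beta, 0.0)
    se = np.where(sxx > 0, se, np.sqrt((yc ** 2).sum() / dof))
    from scipy.stats import t as t_dist

    p = 2 * t_dist.sf(np.abs(beta / se), dof)
    out = genotypes.variants[["variant_id", "chrom", "pos", "ref", "alt"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["p"] = p
    out["N"] = n_gwas
    out["case_fraction"] = 0.0
    out["maf"] = genotypes.maf()
    return out


def write_fixture(
    out_dir: str | Path,
    genotypes: GenotypeMatrix,
    kinship: KinshipMatrix,
    adata: AnnData,
    design: EffectDesign,
    gwas: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write all fixtures as plain text; round-trips through the ingest module.

    Genotypes go to VCFv4.2 (GT, one sample per donor), counts to MatrixMarket
    plus ``genes.tsv``/``cells.tsv``, truth to ``truth_design.tsv``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    vcf = out / "genotypes.vcf"
    gt_codes = {0: "0/0", 1: "0/1", 2: "1/1"}
    with open(vcf, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=scqtl-synthdata\n")
        for chrom in pd.unique(genotypes.variants["chrom"]):
            maxpos = int(genotypes.variants.loc[genotypes.variants["chrom"] == chrom, "pos"].max())
            fh.write(f"##contig=<ID={chrom},length={maxpos + 1000}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, genotypes.donors)) + "\n")
        g_int = np.rint(genotypes.dosages).astype(int)
        order = genotypes.variants.sort_values(["chrom", "pos"]).index
        for j in order:
            v = genotypes.variants.loc[j]
            gts = "\t".join(gt_codes[int(g)] for g in g_int[:, j])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gts}\n")
    paths["vcf"] = vcf

    mtx = out / "counts.mtx"
    X = sp.coo_matrix(adata.X)
    X = sp.coo_matrix((np.asarray(X.data, dtype=np.int64), (X.row, X.col)), shape=X.shape)
    scipy.io.mmwrite(str(mtx), X, field="integer")
    paths["mtx"] = mtx

    genes = adata.var.reset_index().rename(columns={"index": "gene_id"})
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    paths["genes"] = out / "genes.tsv"
    cells = adata.obs.reset_index().rename(columns={"index": "cell_id"})
    cells.to_csv(out / "cells.tsv", sep="\t", index=False)
    paths["cells"] = out / "cells.tsv"

    design.to_frame().to_csv(out / "truth_design.tsv", sep="\t", index=False)
    paths["truth"] = out / "truth_design.tsv"

    kdf = pd.DataFrame(kinship.values, index=kinship.donors, columns=kinship.donors)
    kdf.to_csv(out / "kinship.tsv", sep="\t")
    paths["kinship"] = out / "kinship.tsv"

    if gwas is not None:
        gwas.to_csv(out / "gwas.tsv", sep="\t", index=False)
        paths["gwas"] = out / "gwas.tsv"
    return paths
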