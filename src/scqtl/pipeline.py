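"""End-to-end orchestration: simulate/ingest -> scans -> shrinkage ->
classification -> colocalization, with a reproducibility manifest."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import coloc as cl
from . import ingest, lmm, mash, synthdata
from .config import PipelineConfig

log = logging.getLogger(__name__)

# fixed offsets fan the global seed out to independent stage streams
SEED_OFFSETS = {"simulate": 0, "mash": 101, "gwas": 211, "null": 307}


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> Path:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")
    return path


def _simulate_inputs(cfg: PipelineConfig, out: Path) -> dict[str, Path]:
    s = cfg.simulate
    ct_names = ["AT2", "AT1", "Ciliated", "Macrophage", "Tcell", "Fibroblast"][: s.n_cell_types]
    sim = synthdata.SimConfig(
        seed=cfg.seed + SEED_OFFSETS["simulate"],
        n_donors=s.n_donors,
        frac_diseased=s.frac_diseased,
        n_genes=s.n_genes,
        snps_per_gene=s.snps_per_gene,
        cell_types=[synthdata.CellTypeSpec(n, s.mean_cells) for n in ct_names],
    )
    G, K = synthdata.simulate_genotypes(sim)
    design = synthdata.random_design(
        G, sim,
        {"global": s.n_global, "multi": s.n_multi, "unique": s.n_unique,
         "sign_flip": s.n_sign_flip, "interaction_only": s.n_interaction_only},
        effect_size=s.effect_size,
    )
    adata = synthdata.simulate_cells(G, K, design, sim)
    gwas = None
    if cfg.coloc.enabled and len(design.eqtls):
        causal = design.eqtls["variant_id"].iloc[0]
        gwas = synthdata.simulate_gwas_stats(
            G, causal, n_gwas=2000, h2_snp=0.05, mode="shared",
            seed=cfg.seed + SEED_OFFSETS["gwas"],
        )
    fixdir = out / "fixtures"
    return synthdata.write_fixture(fixdir, G, K, adata, design, gwas=gwas)


def run_pipeline(cfg: PipelineConfig) -> Path:
    """Execute the configured stages in order; returns the run directory.

    Intermediate artifacts are TSV files; a ``manifest.json`` records inputs,
    parameters, per-stage row counts and output checksums so identical
    configurations can be verified to reproduce identical artifacts.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    manifest: dict = {"config": cfg.to_dict(), "seed": cfg.seed, "stages": {}, "outputs": {}}
    paths = dict(
        vcf=cfg.paths.vcf, mtx=cfg.paths.mtx, cells=cfg.paths.cells,
        genes=cfg.paths.genes, gwas=cfg.paths.gwas,
    )
    try:
        if cfg.simulate.enabled:
            fix = _simulate_inputs(cfg, out)
            paths.update({k: str(v) for k, v in fix.items() if k in
                          ("vcf", "mtx", "cells", "genes", "gwas")})
            manifest["stages"]["simulate"] = {"fixtures": {k: str(v) for k, v in fix.items()}}
        for k in ("vcf", "mtx", "cells", "genes"):
            if not paths.get(k):
                raise ValueError(f"missing required input '{k}'")

        # --- ingest + pseudobulk
        G = ingest.read_genotypes(paths["vcf"])
        Gf = ingest.filter_variants(
            G, cfg.ingest.maf_min, cfg.ingest.hwe_p_min,
            cfg.ingest.ld_window, cfg.ingest.ld_step, cfg.ingest.ld_r2,
        )
        adata = ingest.read_cell_counts(paths["mtx"], paths["cells"], paths["genes"])
        adata = ingest.qc_cells(adata, cfg.ingest.mito_max)
        genes_kept = ingest.filter_genes(adata, cfg.ingest.min_cell_frac, cfg.ingest.min_mean_count)
        adata = adata[:, genes_kept].copy()
        adata = ingest.normalize_log(adata)
        pb = ingest.pseudobulk_aggregate(adata, cfg.ingest.min_cells, cfg.ingest.min_donors)
        annotation = adata.var.reset_index().rename(columns={"index": "gene_id"})
        manifest["stages"]["ingest"] = {
            "variants": Gf.n_variants, "cells": adata.n_obs,
            "genes": len(genes_kept), "cell_types": pb.cell_types,
        }
        kinship = lmm.compute_kinship(Gf)

        # --- additive scans
        assoc_add = []
        resid_store = {}
        for ct in pb.cell_types:
            m = pb[ct]
            Yt = lmm.transform_matrix(m.expr)
            pcs = lmm.expression_pcs(Yt, cfg.mapping.n_pcs)
            Yr = lmm.residualize(Yt, pcs)
            fits = lmm.fit_null_per_gene(Yr, kinship, m.n_cells)
            rows = lmm.scan_cis_additive(
                Yr, Gf, annotation, fits, window=cfg.mapping.window,
                cell_type=ct, pcs=pcs,
            )
            assoc_add.append(rows)
            resid_store[ct] = (Yt, pcs, m)
        assoc_add = pd.concat(assoc_add, ignore_index=True)
        _write_tsv(assoc_add, out / "assoc_additive.tsv")
        manifest["stages"]["additive_scan"] = {"rows": len(assoc_add)}

        # --- interaction scans
        assoc_int = pd.DataFrame()
        if cfg.interaction:
            rows_int = []
            for ct in pb.cell_types:
                Yt, pcs, m = resid_store[ct]
                n_case = (m.disease.astype(str) == "ILD").sum()
                n_ctrl = len(m.disease) - n_case
                if min(n_case, n_ctrl) < cfg.mapping.min_donors_per_group:
                    log.info("cell type %s excluded from interaction mapping", ct)
                    continue
                fits = lmm.fit_null_per_gene(Yt, kinship, m.n_cells)
                rows_int.append(
                    lmm.scan_cis_interaction(
                        Yt, Gf, annotation, m.disease, pcs, fits,
                        window=cfg.mapping.window, cell_type=ct,
                        group_maf_min=cfg.mapping.group_maf_min,
                        min_donors_per_group=cfg.mapping.min_donors_per_group,
                    )
                )
            if rows_int:
                assoc_int = pd.concat(rows_int, ignore_index=True)
                _write_tsv(assoc_int, out / "assoc_interaction.tsv")
            manifest["stages"]["interaction_scan"] = {"rows": len(assoc_int)}

        # --- mash + classification per term
        results = {}
        for term, assoc in (("additive", assoc_add), ("interaction", assoc_int)):
            if assoc.empty or assoc["cell_type"].nunique() < 2:
                continue
            stats = mash.MultiConditionStats.from_assoc(assoc)
            model, post = mash.run_mash(
                stats, strong_lfsr=cfg.mash.strong_lfsr, n_pcs=cfg.mash.n_pcs,
                ed_iters=cfg.mash.ed_iters, subset_size=cfg.mash.subset_size,
                seed=cfg.seed + SEED_OFFSETS["mash"],
            )
            model.save(out / f"mash_model_{term}.json")
            _write_tsv(post.post_mean, out / f"posterior_mean_{term}.tsv", index=True)
            _write_tsv(post.post_sd, out / f"posterior_sd_{term}.tsv", index=True)
            _write_tsv(post.lfsr, out / f"lfsr_{term}.tsv", index=True)
            mask = clf.call_significance(post.lfsr, cfg.classify.primary, cfg.classify.secondary)
            tss = assoc.assign(assoc_id=assoc["gene"] + ":" + assoc["variant"]) \
                .drop_duplicates("assoc_id").set_index("assoc_id")["tss_dist"]
            top = clf.select_top(post.post_mean, post.lfsr, mask, tss_dist=tss)
            if not top.empty:
                labels = clf.classify_table(mask, buffer=cfg.classify.buffer)
                top["class"] = labels.reindex(top["assoc_id"]).to_numpy()
                sharing = clf.pairwise_sharing(
                    post.post_mean, mask, pd.Index(top["assoc_id"].unique()),
                    factor=cfg.classify.share_factor,
                )
                pruned = clf.prune_top(top, post.post_mean, mask,
                                       dist_threshold=cfg.classify.prune_dist)
                _write_tsv(top, out / f"top_eqtl_{term}.tsv")
                _write_tsv(sharing, out / f"sharing_matrix_{term}.tsv", index=True)
                _write_tsv(pruned, out / f"pruned_top_eqtl_{term}.tsv")
            results[term] = (post, mask, top if not top.empty else None)
            manifest["stages"][f"mash_{term}"] = {
                "associations": stats.n, "significant": int(mask.any(axis=1).sum()),
                "top_eqtl": 0 if top.empty else len(top),
            }

        # --- colocalization
        if cfg.coloc.enabled and paths.get("gwas") and "additive" in results:
            gwas = pd.read_csv(paths["gwas"], sep="\t")
            post, mask, top = results["additive"]
            coloc_rows = []
            egenes = sorted(set(top["gene"])) if top is not None else []
            var_meta = Gf.variants.set_index("variant_id")
            maf = pd.Series(Gf.maf(), index=Gf.variants["variant_id"])
            for gene in egenes:
                gene_ids = [i for i in post.post_mean.index if i.startswith(gene + ":")]
                for ct in post.post_mean.columns:
                    sub = pd.DataFrame(
                        {
                            "variant": [i.split(":", 1)[1] for i in gene_ids],
                            "beta": post.post_mean.loc[gene_ids, ct].to_numpy(),
                            "se": np.maximum(post.post_sd.loc[gene_ids, ct].to_numpy(), 1e-6),
                        }
                    )
                    sub["chrom"] = var_meta.loc[sub["variant"], "chrom"].to_numpy()
                    sub["pos"] = var_meta.loc[sub["variant"], "pos"].to_numpy()
                    sub["ref"] = var_meta.loc[sub["variant"], "ref"].to_numpy()
                    sub["alt"] = var_meta.loc[sub["variant"], "alt"].to_numpy()
                    sub["maf"] = maf.loc[sub["variant"]].to_numpy()
                    merged = cl.harmonize(sub, gwas)
                    res = cl.coloc_abf(
                        merged, cfg.coloc.p1, cfg.coloc.p2, cfg.coloc.p12,
                        cfg.coloc.prior_sd_eqtl, cfg.coloc.prior_sd_gwas,
                        cfg.coloc.min_shared,
                    )
                    coloc_rows.append({"gene": gene, "cell_type": ct, **res.as_dict()})
            coloc_df = pd.DataFrame(coloc_rows)
            if not coloc_df.empty:
                _write_tsv(coloc_df, out / "coloc_results.tsv")
            manifest["stages"]["coloc"] = {"rows": len(coloc_df)}
    except Exception as exc:  # partial manifest on failure
        manifest["error"] = repr(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        raise

    for f in sorted(out.glob("*.tsv")):
        manifest["outputs"][f.name] = _sha256(f)
    manifest["elapsed_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    return out
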