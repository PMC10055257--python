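"""Generator properties: determinism, LD/kinship structure, planted-effect
recoverability, GWAS statistics, fixture round-trips."""

import numpy as np
import pandas as pd
import pytest

from scqtl import ingest
from scqtl import synthdata as sd


def _ols_slope(y, x):
    X = np.column_stack([np.ones(len(x)), x])
    return np.linalg.lstsq(X, y, rcond=None)[0][1]


def pseudobulk_means(adata, cell_type, gene):
    obs = adata.obs
    sub = obs.index[obs["cell_type"] == cell_type]
    gi = adata.var_names.get_loc(gene)
    X = adata[sub, :].X
    df = pd.DataFrame(
        {"donor": obs.loc[sub, "donor"].to_numpy(),
         "expr": np.log2(np.asarray(X[:, gi].todense()).ravel() + 1)}
    )
    return df.groupby("donor")["expr"].mean()


class TestGenotypes:
    def test_seed_determinism(self):
        cfg = sd.SimConfig(seed=3, n_donors=40, n_genes=5, snps_per_gene=8)
        G1, K1 = sd.simulate_genotypes(cfg)
        G2, K2 = sd.simulate_genotypes(cfg)
        np.testing.assert_array_equal(G1.dosages, G2.dosages)
        np.testing.assert_array_equal(K1.values, K2.values)
        pd.testing.assert_frame_equal(G1.variants, G2.variants)

    def test_dosages_are_genotype_calls(self):
        cfg = sd.SimConfig(seed=3, n_donors=40, n_genes=3, snps_per_gene=5)
        G, _ = sd.simulate_genotypes(cfg)
        assert set(np.unique(G.dosages)) <= {0.0, 1.0, 2.0}

    def test_unrelated_family_gives_identity_kinship(self):
        cfg = sd.SimConfig(seed=5, n_donors=20, n_genes=3, snps_per_gene=5,
                           n_families=1, family_size=20, relatedness=0.0)
        _, K = sd.simulate_genotypes(cfg)
        np.testing.assert_allclose(K.values, np.eye(20))

    def test_family_kinship_block(self):
        cfg = sd.SimConfig(seed=5, n_donors=10, n_genes=3, snps_per_gene=5,
                           n_families=2, family_size=3, relatedness=0.5)
        _, K = sd.simulate_genotypes(cfg)
        assert K.values[0, 1] == 0.5 and K.values[0, 3] == 0.0
        assert np.all(np.diag(K.values) == 1.0)

    def test_adjacent_ld_matches_configuration(self):
        # Monte-Carlo: copy probability 0.9 -> adjacent dosage r^2 ~ 0.81
        cfg = sd.SimConfig(seed=11, n_donors=500, n_genes=10, snps_per_gene=10,
                           ld_block_size=5, ld_corr=0.9)
        G, _ = sd.simulate_genotypes(cfg)
        r2 = []
        for g in range(cfg.n_genes):
            base = g * cfg.snps_per_gene
            for j in range(cfg.snps_per_gene - 1):
                if (j + 1) % cfg.ld_block_size == 0:
                    continue  # block boundary
                a, b = G.dosages[:, base + j], G.dosages[:, base + j + 1]
                if a.std() > 0 and b.std() > 0:
                    r2.append(np.corrcoef(a, b)[0, 1] ** 2)
        assert abs(np.mean(r2) - 0.81) < 0.1

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            sd.SimConfig(seed=1, n_donors=0)
        with pytest.raises(ValueError):
            sd.SimConfig(seed=1, maf_range=(0.0, 0.6))


class TestCells:
    def test_null_gene_mean_matches_baseline(self):
        cfg = sd.SimConfig(
            seed=2, n_donors=30, n_genes=4, snps_per_gene=4,
            nb_dispersion=0.0, donor_re_sd=0.0, baseline_log2=(5.0, 5.0),
            cell_types=[sd.CellTypeSpec("A", 200.0)],
        )
        G, K = sd.simulate_genotypes(cfg)
        design = sd.random_design(G, cfg, {})
        adata = sd.simulate_cells(G, K, design, cfg)
        mean_count = np.asarray(adata.X.mean(axis=0)).ravel()
        np.testing.assert_allclose(mean_count, 2.0 ** 5, rtol=0.05)

    def test_planted_additive_slope_recovered(self):
        cfg = sd.SimConfig(
            seed=4, n_donors=100, n_genes=50, snps_per_gene=6,
            cell_types=[sd.CellTypeSpec("A", 50.0)],
        )
        G, K = sd.simulate_genotypes(cfg)
        design = sd.random_design(G, cfg, {"global": 1}, effect_size=1.0, seed=9)
        adata = sd.simulate_cells(G, K, design, cfg)
        gene = design.eqtls["gene_id"].iloc[0]
        causal = design.eqtls["variant_id"].iloc[0]
        pb = pseudobulk_means(adata, "A", gene)
        dose = pd.Series(
            G.dosages[:, G.variants.index[G.variants["variant_id"] == causal][0]],
            index=G.donors,
        ).loc[pb.index]
        slope = _ols_slope(pb.to_numpy(), dose.to_numpy())
        truth = design.beta.loc[gene, "A"]
        assert abs(slope - truth) < 0.15 * abs(truth) + 0.0 or abs(slope - truth) < 0.15

    def test_interaction_only_effect_group_specific(self):
        cfg = sd.SimConfig(
            seed=6, n_donors=120, n_genes=30, snps_per_gene=6, frac_diseased=0.5,
            cell_types=[sd.CellTypeSpec("A", 50.0)],
        )
        G, K = sd.simulate_genotypes(cfg)
        design = sd.random_design(G, cfg, {"interaction_only": 1},
                                  interaction_size=1.0, seed=13)
        adata = sd.simulate_cells(G, K, design, cfg)
        gene = design.eqtls["gene_id"].iloc[0]
        causal = design.eqtls["variant_id"].iloc[0]
        pb = pseudobulk_means(adata, "A", gene)
        vj = G.variants.index[G.variants["variant_id"] == causal][0]
        dose = pd.Series(G.dosages[:, vj], index=G.donors).loc[pb.index]
        status = pb.index.map(dict(adata.uns["disease_by_donor"]))
        ild = status == "ILD"
        slope_ild = _ols_slope(pb[ild].to_numpy(), dose[ild].to_numpy())
        slope_ctl = _ols_slope(pb[~ild].to_numpy(), dose[~ild].to_numpy())
        bgd = design.beta_gd.loc[gene, "A"]
        assert abs(slope_ctl) < 0.15
        assert abs((slope_ild - slope_ctl) - bgd) < 0.3 * abs(bgd)

    def test_sign_recovery_rate(self):
        # planted |beta|=1 effects: OLS recovers the sign in >= 95% of plants
        correct = 0
        total = 0
        for rep in range(3):
            cfg = sd.SimConfig(
                seed=100 + rep, n_donors=100, n_genes=40, snps_per_gene=5,
                cell_types=[sd.CellTypeSpec("A", 50.0)],
            )
            G, K = sd.simulate_genotypes(cfg)
            design = sd.random_design(G, cfg, {"global": 4}, effect_size=1.0, seed=rep)
            adata = sd.simulate_cells(G, K, design, cfg)
            for _, r in design.eqtls.iterrows():
                pb = pseudobulk_means(adata, "A", r["gene_id"])
                vj = G.variants.index[G.variants["variant_id"] == r["variant_id"]][0]
                dose = pd.Series(G.dosages[:, vj], index=G.donors).loc[pb.index]
                slope = _ols_slope(pb.to_numpy(), dose.to_numpy())
                correct += np.sign(slope) == np.sign(design.beta.loc[r["gene_id"], "A"])
                total += 1
        assert correct / total >= 0.95

    def test_design_invariants_enforced(self):
        genes, cts = ["G0000"], ["A", "B"]
        z = pd.DataFrame(0.0, index=pd.Index(genes, name="gene_id"), columns=cts)
        bad = z.copy()
        bad.loc["G0000", "A"] = 1.0  # "global" but one zero entry
        with pytest.raises(ValueError):
            sd.EffectDesign(
                eqtls=pd.DataFrame([{"gene_id": "G0000", "variant_id": "v", "pattern": "global"}]),
                beta=bad, beta_gd=z.copy(), beta_disease=z.copy(),
            )


@pytest.fixture(scope="module")
def panel():
    cfg = sd.SimConfig(seed=21, n_donors=300, n_genes=1, snps_per_gene=60,
                       ld_block_size=6, ld_corr=0.8)
    G, _ = sd.simulate_genotypes(cfg)
    return G


class TestGwas:
    def test_null_z_uniform(self, panel):
        from scipy.stats import kstest

        stats = sd.simulate_gwas_stats(panel, panel.variants["variant_id"].iloc[0],
                                       n_gwas=400, mode="null", seed=5)
        assert stats["se"].min() > 0
        # null p-values approximately uniform across variants
        assert kstest(stats["p"], "uniform").pvalue > 0.01

    def test_shared_top_hit_tags_causal(self, panel):
        causal = panel.variants["variant_id"].iloc[30]
        stats = sd.simulate_gwas_stats(panel, causal, n_gwas=800, h2_snp=0.15,
                                       mode="shared", seed=6)
        top = stats.loc[(stats["beta"] / stats["se"]).abs().idxmax(), "variant_id"]
        ci = panel.variants.index[panel.variants["variant_id"] == causal][0]
        ti = panel.variants.index[panel.variants["variant_id"] == top][0]
        r = np.corrcoef(panel.dosages[:, ci], panel.dosages[:, ti])[0, 1]
        assert r ** 2 > 0.8

    def test_unknown_variant_rejected(self, panel):
        with pytest.raises(KeyError):
            sd.simulate_gwas_stats(panel, "nope", mode="shared", seed=1)


class TestFixtureRoundTrip:
    def test_write_read_identity(self, small_cohort, tmp_path):
        G, K, design, adata = small_cohort
        paths = sd.write_fixture(tmp_path, G, K, adata, design)
        G2 = ingest.read_genotypes(paths["vcf"])
        d1 = G.dosage_frame().sort_index(axis=1)
        d2 = G2.dosage_frame().sort_index(axis=1)
        pd.testing.assert_frame_equal(d1, d2, check_dtype=False)
        cells = pd.read_csv(paths["cells"], sep="\t")
        assert len(cells) == adata.n_obs
        adata2 = ingest.read_cell_counts(paths["mtx"], paths["cells"], paths["genes"])
        assert (adata2.X != adata.X).nnz == 0
        truth = sd.EffectDesign.from_frame(pd.read_csv(paths["truth"], sep="\t"))
        planted = truth.beta.index
        pd.testing.assert_frame_equal(
            truth.beta.sort_index(axis=1),
            design.beta.loc[planted].sort_index(axis=1),
            check_names=False,
        )

    def test_vcf_grammar_parses(self, small_cohort, tmp_path):
        from cyvcf2 import VCF

        G, K, design, adata = small_cohort
        paths = sd.write_fixture(tmp_path, G, K, adata, design)
        records = list(VCF(str(paths["vcf"])))
        assert len(records) == G.n_variants
        assert all(len(r.ALT) == 1 for r in records)
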