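"""QC filter boundaries, normalization, and pseudo-bulk aggregation rules."""

import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp
from anndata import AnnData

from scqtl import ingest
from scqtl.containers import GenotypeMatrix


def _geno(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    variants = pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(m)],
            "chrom": chrom,
            "pos": positions if positions is not None else np.arange(1, m + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    donors = np.array([f"D{i}" for i in range(dosages.shape[0])], dtype=object)
    return GenotypeMatrix(donors, variants, dosages)


def _cells(counts, mito=None, donors=None, cell_types=None, disease=None):
    counts = np.asarray(counts)
    n = counts.shape[0]
    obs = pd.DataFrame(
        {
            "donor": donors if donors is not None else ["D0"] * n,
            "cell_type": cell_types if cell_types is not None else ["A"] * n,
            "disease": disease if disease is not None else ["control"] * n,
            "mito_frac": mito if mito is not None else [0.05] * n,
        },
        index=[f"c{i}" for i in range(n)],
    )
    var = pd.DataFrame(index=[f"g{j}" for j in range(counts.shape[1])])
    return AnnData(X=sp.csr_matrix(counts), obs=obs, var=var)


class TestReadGenotypes:
    def test_vcf_gt_encoding_and_imputation(self, tmp_path):
        vcf = tmp_path / "t.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\tS4\tS5\n"
            "1\t100\tv1\tA\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\t0/1\t0/0\n"
            "1\t200\tv2\tA\tG\t.\tPASS\t.\tGT\t./.\t0/1\t1/1\t0/1\t0/0\n"
            "1\t300\tv3\tA\tG,T\t.\tPASS\t.\tGT\t0/0\t0/1\t0/2\t0/1\t0/0\n"
        )
        G = ingest.read_genotypes(vcf)
        # triallelic v3 skipped
        assert list(G.variants["variant_id"]) == ["v1", "v2"]
        np.testing.assert_array_equal(G.dosages[:, 0], [0, 1, 2, 1, 0])
        # missing genotype imputed to mean of observed = (1+2+1+0)/4 = 1.0
        assert G.dosages[0, 1] == pytest.approx(1.0)

    def test_dosage_tsv(self, tmp_path):
        f = tmp_path / "d.tsv"
        pd.DataFrame(
            [[0, 1], [2, 1]], index=["D0", "D1"], columns=["1:100:A:G", "1:200:A:G"]
        ).to_csv(f, sep="\t")
        G = ingest.read_genotypes(f)
        assert G.n_donors == 2 and G.variants["pos"].tolist() == [100, 200]

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            ingest.read_genotypes("/nonexistent.vcf")


class TestFilterVariants:
    def test_maf_boundary_strict(self):
        rng = np.random.default_rng(0)
        # v0: exactly MAF 0.05 in 100 donors (10 alt alleles); v1: MAF 0.3
        d0 = np.zeros(100)
        d0[:10] = 1.0  # 10/200 alleles
        d1 = rng.binomial(2, 0.3, size=100).astype(float)
        G = _geno(np.column_stack([d0, d1]))
        out = ingest.filter_variants(G, ld_r2=1.1)
        assert list(out.variants["variant_id"]) == ["v1"]

    def test_hwe_violation_removed(self):
        # 50 hom-ref, 50 hom-alt, 0 het: extreme HWE departure, MAF 0.5
        d = np.array([0.0] * 50 + [2.0] * 50)
        ok = np.array([0.0, 1.0, 2.0, 1.0] * 25)  # in equilibrium
        G = _geno(np.column_stack([d, ok]))
        out = ingest.filter_variants(G, ld_r2=1.1)
        assert list(out.variants["variant_id"]) == ["v1"]

    def test_duplicate_variant_pruned(self):
        rng = np.random.default_rng(1)
        d = rng.binomial(2, 0.4, size=200).astype(float)
        G = _geno(np.column_stack([d, d]))
        out = ingest.filter_variants(G)
        assert out.n_variants == 1

    def test_idempotent(self):
        rng = np.random.default_rng(2)
        d = rng.binomial(2, 0.3, size=(100, 20)).astype(float)
        G = _geno(d)
        once = ingest.filter_variants(G)
        twice = ingest.filter_variants(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)


class TestCellQc:
    def test_mito_boundary(self):
        ad = _cells(np.ones((3, 2)), mito=[0.21, 0.20, 0.05])
        out = ingest.qc_cells(ad, mito_max=0.20)
        assert list(out.obs_names) == ["c1", "c2"]  # 0.21 removed, 0.20 kept

    def test_empty_input(self):
        ad = _cells(np.zeros((0, 2)))
        assert ingest.qc_cells(ad).n_obs == 0

    def test_missing_metadata_errors(self):
        ad = _cells(np.ones((2, 2)))
        del ad.obs["mito_frac"]
        with pytest.raises(ValueError):
            ingest.qc_cells(ad)

    def test_idempotent(self):
        ad = _cells(np.ones((5, 2)), mito=[0.25, 0.1, 0.2, 0.3, 0.0])
        once = ingest.qc_cells(ad)
        twice = ingest.qc_cells(once)
        assert list(once.obs_names) == list(twice.obs_names)


class TestGeneFilter:
    def test_expression_fraction_boundary(self):
        # 1000 cells: g0 expressed in 99 (9.9%) removed; g1 in 100 (10%) kept
        X = np.zeros((1000, 2))
        X[:99, 0] = 2.0
        X[:100, 1] = 2.0
        ad = _cells(X)
        kept = ingest.filter_genes(ad, min_cell_frac=0.10, min_mean_count=0.1)
        assert list(kept) == ["g1"]

    def test_mean_count_boundary(self):
        # g0 mean exactly 0.1 retained (exclusion rule is "< 0.1")
        X = np.zeros((10, 2))
        X[0, 0] = 1.0    # mean 0.1, expressed in 10%
        X[0, 1] = 0.5    # mean 0.05
        X[1, 1] = 0.4
        ad = _cells(X)
        kept = ingest.filter_genes(ad, min_cell_frac=0.10, min_mean_count=0.1)
        assert list(kept) == ["g0"]

    def test_exclusion_list(self, tmp_path):
        X = np.ones((10, 2)) * 5
        ad = _cells(X)
        f = tmp_path / "ribo.tsv"
        f.write_text("g1\n")
        kept = ingest.filter_genes(ad, exclude_lists=[f])
        assert list(kept) == ["g0"]

    def test_empty_exclusion_file_allowed(self, tmp_path):
        X = np.ones((10, 1)) * 5
        ad = _cells(X)
        f = tmp_path / "empty.tsv"
        f.write_text("")
        kept = ingest.filter_genes(ad, exclude_lists=[f])
        assert list(kept) == ["g0"]


class TestNormalize:
    def test_equal_libraries_log2_plus_one(self):
        X = np.array([[2, 2], [1, 3], [3, 1]], dtype=float)
        ad = _cells(X)
        out = ingest.normalize_log(ad, pool_by=None)
        np.testing.assert_allclose(out.obs["size_factor"], 1.0)
        np.testing.assert_allclose(
            np.asarray(out.layers["lognorm"].todense()), np.log2(X + 1)
        )

    def test_scale_invariance(self):
        # doubling one cell's counts doubles its size factor, so normalized
        # rates change only by the global rescaling constant shared by all cells
        X = np.array([[2, 4], [1, 2], [4, 8]], dtype=float)
        Xd = X.copy()
        Xd[0] *= 2
        a = ingest.normalize_log(_cells(X), pool_by=None)
        b = ingest.normalize_log(_cells(Xd), pool_by=None)
        rate_a = X / a.obs["size_factor"].to_numpy()[:, None]
        rate_b = Xd / b.obs["size_factor"].to_numpy()[:, None]
        ratio = rate_b / rate_a
        np.testing.assert_allclose(ratio, ratio[0, 0], rtol=1e-10)

    def test_hand_computed_toy(self):
        X = np.array([[1, 1], [2, 2], [4, 4]], dtype=float)
        lib = X.sum(axis=1)
        sf = lib / np.exp(np.mean(np.log(lib)))
        sf = sf / sf.mean()
        expected = np.log2(X / sf[:, None] + 1)
        out = ingest.normalize_log(_cells(X), pool_by=None)
        np.testing.assert_allclose(np.asarray(out.layers["lognorm"].todense()), expected)

    def test_zero_library_dropped(self):
        X = np.array([[0, 0], [1, 2]], dtype=float)
        with pytest.warns(UserWarning):
            out = ingest.normalize_log(_cells(X), pool_by=None)
        assert out.n_obs == 1


class TestPseudobulk:
    def _adata(self):
        # donor D0: 6 cells (kept), D1: 4 cells (dropped by min_cells=5)
        counts = np.ones((10, 2))
        donors = ["D0"] * 6 + ["D1"] * 4
        ad = _cells(counts, donors=donors)
        ad.layers["lognorm"] = sp.csr_matrix(
            np.array([[2.0, 1.0]] * 3 + [[4.0, 1.0]] * 3 + [[9.0, 9.0]] * 4)
        )
        return ad

    def test_mean_and_min_cells(self):
        pb = ingest.pseudobulk_aggregate(self._adata(), min_cells=5, min_donors=1)
        m = pb["A"]
        assert list(m.donors) == ["D0"]
        assert m.expr.loc["D0", "g0"] == pytest.approx(3.0)  # mean of {2,2,2,4,4,4}
        assert m.n_cells.loc["D0"] == 6

    def test_min_donors_drops_cell_type(self):
        with pytest.raises(ValueError):
            ingest.pseudobulk_aggregate(self._adata(), min_cells=5, min_donors=2)

    def test_conservation_and_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 200
        counts = rng.poisson(5, size=(n, 3)).astype(float)
        donors = rng.choice([f"D{i}" for i in range(8)], size=n)
        cts = rng.choice(["A", "B"], size=n)
        ad = _cells(counts, donors=donors, cell_types=cts)
        ad.layers["lognorm"] = sp.csr_matrix(np.log2(counts + 1))
        pb = ingest.pseudobulk_aggregate(ad, min_cells=5, min_donors=2)
        for ct in pb.cell_types:
            kept = 0
            for d in pb[ct].donors:
                kept += ((ad.obs["donor"] == d) & (ad.obs["cell_type"] == ct)).sum()
            assert pb[ct].n_cells.sum() == kept
        perm = rng.permutation(n)
        ad2 = ad[perm].copy()
        pb2 = ingest.pseudobulk_aggregate(ad2, min_cells=5, min_donors=2)
        for ct in pb.cell_types:
            pd.testing.assert_frame_equal(pb[ct].expr, pb2[ct].expr)
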