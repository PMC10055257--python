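"""Shared in-memory containers for genotype, kinship and pseudo-bulk data.

Cell-level counts use :class:`anndata.AnnData` directly (cells in ``obs``,
genes in ``var``); only the structures without an established container are
defined here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hwe import hwe_exact_test

VARIANT_COLUMNS = ["variant_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Donor x variant dosage matrix with variant annotations.

    Parameters
    ----------
    donors
        Donor identifiers, one per dosage row.
    variants
        One row per variant with at least ``variant_id, chrom, pos, ref, alt``
        (1-based positions). Extra columns are preserved through subsetting.
    dosages
        ``(n_donors, n_variants)`` alt-allele dosages in ``[0, 2]``.
    """

    donors: np.ndarray
    variants: pd.DataFrame
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors, dtype=object)
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.donors), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.donors)} donors x {len(self.variants)} variants"
            )
        missing = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing:
            raise ValueError(f"variant table lacks columns {missing}")
        if self.variants["variant_id"].duplicated().any():
            raise ValueError("duplicate variant ids")
        if np.nanmin(self.dosages, initial=0.0) < 0 or np.nanmax(self.dosages, initial=0.0) > 2:
            raise ValueError("dosages outside [0, 2]")
        self.variants = self.variants.reset_index(drop=True)

    @property
    def n_donors(self) -> int:
        return len(self.donors)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def maf(self) -> np.ndarray:
        """Per-variant minor allele frequency from mean dosage."""
        p = self.dosages.mean(axis=0) / 2.0
        return np.minimum(p, 1.0 - p)

    def hwe_p(self, midp: bool = False) -> np.ndarray:
        """Per-variant Hardy-Weinberg exact-test p (dosages rounded to 0/1/2)."""
        g = np.rint(self.dosages).astype(int)
        out = np.empty(self.n_variants)
        for j in range(self.n_variants):
            n_het = int((g[:, j] == 1).sum())
            n_hom_alt = int((g[:, j] == 2).sum())
            n_hom_ref = int((g[:, j] == 0).sum())
            out[j] = hwe_exact_test(n_het, n_hom_ref, n_hom_alt, midp=midp)
        return out

    def subset_variants(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return GenotypeMatrix(
            donors=self.donors,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosages=self.dosages[:, idx],
        )

    def subset_donors(self, donor_ids) -> "GenotypeMatrix":
        order = {d: i for i, d in enumerate(self.donors)}
        idx = np.array([order[d] for d in donor_ids], dtype=int)
        return GenotypeMatrix(
            donors=self.donors[idx], variants=self.variants.copy(), dosages=self.dosages[idx]
        )

    def dosage_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosages, index=self.donors, columns=self.variants["variant_id"].to_numpy()
        )


@dataclass
class KinshipMatrix:
    """Symmetric donor x donor relatedness matrix."""

    donors: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.donors = np.asarray(self.donors, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.donors)
        if self.values.shape != (n, n):
            raise ValueError("kinship shape does not match donor count")
        if not np.allclose(self.values, self.values.T, atol=1e-8):
            raise ValueError("kinship matrix is not symmetric")
        w = np.linalg.eigvalsh(self.values)
        if w.min() < -1e-8:
            raise ValueError(f"kinship matrix is not PSD (min eigenvalue {w.min():.3g})")

    def align(self, donor_ids) -> np.ndarray:
        order = {d: i for i, d in enumerate(self.donors)}
        idx = np.array([order[d] for d in donor_ids], dtype=int)
        return self.values[np.ix_(idx, idx)]


@dataclass
class PseudobulkMatrix:
    """Per-cell-type donor x gene mean log2 expression with donor metadata."""

    cell_type: str
    expr: pd.DataFrame           # donors x genes
    n_cells: pd.Series           # per-donor aggregated cell count
    disease: pd.Series           # per-donor label, e.g. "ILD"/"control"

    def __post_init__(self) -> None:
        if not self.expr.index.equals(self.n_cells.index):
            raise ValueError("n_cells index must match expression donors")
        if not self.expr.index.equals(self.disease.index):
            raise ValueError("disease index must match expression donors")

    @property
    def donors(self) -> pd.Index:
        return self.expr.index


@dataclass
class PseudobulkSet:
    """Pseudo-bulk matrices keyed by cell type."""

    matrices: dict[str, PseudobulkMatrix] = field(default_factory=dict)

    def __getitem__(self, cell_type: str) -> PseudobulkMatrix:
        return self.matrices[cell_type]

    def __iter__(self):
        return iter(self.matrices)

    def __len__(self) -> int:
        return len(self.matrices)

    @property
    def cell_types(self) -> list[str]:
        return list(self.matrices)
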