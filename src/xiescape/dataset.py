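"""Allele-resolved single-nucleus count bundles.

The pipeline's sole input is a pair of cell x gene count matrices from an
F1-hybrid cross in which every allele-informative read has been assigned to
one parental genome: the active-X (reference) strain or the inactive-X
(alternate) strain.  In the nonrandom-XCI mouse model the reference strain
(M. musculus) always carries the active X, so inactive-strain reads on the
X chromosome are candidate escape signal.

On disk a dataset is a directory bundle::

    xa_strain.mtx   Matrix Market, integer, genes x cells (orientation in a
                    comment line), reads assigned to the active-X strain
    xi_strain.mtx   same shape, reads assigned to the inactive-X strain
    cells.tsv       barcode, cell_type, sample_id, age_group
    genes.tsv       gene_id, chromosome

In memory matrices are CSR, cells x genes.  Stored counts are integers and
are never mutated by downstream normalization.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

XA_MATRIX = "xa_strain.mtx"
XI_MATRIX = "xi_strain.mtx"
CELLS_TSV = "cells.tsv"
GENES_TSV = "genes.tsv"

CELL_COLUMNS = ["barcode", "cell_type", "sample_id", "age_group"]
GENE_COLUMNS = ["gene_id", "chromosome"]
AGE_GROUPS = ("young", "old")

_ORIENTATION_GENES_CELLS = "orientation: genes x cells"
_ORIENTATION_CELLS_GENES = "orientation: cells x genes"


class BundleError(Exception):
    """Problem with an on-disk dataset bundle."""


class MissingComponentError(BundleError):
    """A required bundle file is absent."""


class InconsistentBundleError(BundleError):
    """Bundle components disagree on dimensions."""


@dataclass
class AlleleCountDataset:
    """Paired allele count matrices plus cell and gene annotation.

    ``counts_xa`` and ``counts_xi`` are cells x genes sparse integer
    matrices holding reads assigned to the active-X strain and inactive-X
    strain genomes respectively; rows align with ``cells`` and columns
    with ``genes``.
    """

    counts_xa: sp.csr_matrix
    counts_xi: sp.csr_matrix
    cells: pd.DataFrame
    genes: pd.DataFrame

    @property
    def n_cells(self) -> int:
        return self.counts_xa.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts_xa.shape[1]

    def x_mask(self) -> np.ndarray:
        """Boolean mask over genes, True for X-linked genes."""
        return (self.genes["chromosome"].to_numpy() == "X")

    def equals(self, other: "AlleleCountDataset") -> bool:
        if self.counts_xa.shape != other.counts_xa.shape:
            return False
        if (self.counts_xa != other.counts_xa).nnz != 0:
            return False
        if (self.counts_xi != other.counts_xi).nnz != 0:
            return False
        return self.cells.reset_index(drop=True).equals(
            other.cells.reset_index(drop=True)
        ) and self.genes.reset_index(drop=True).equals(
            other.genes.reset_index(drop=True)
        )


def validate_dataset(ds: AlleleCountDataset) -> list[str]:
    """Check every dataset invariant; return one message per violation.

    An empty report means the dataset is valid.  Messages name the broken
    invariant and, where meaningful, the offending index or label.
    """
    report: list[str] = []
    if ds.counts_xa.shape != ds.counts_xi.shape:
        report.append(
            "dimension mismatch: xa_strain is "
            f"{ds.counts_xa.shape}, xi_strain is {ds.counts_xi.shape}"
        )
        return report  # further checks assume aligned shapes
    n_cells, n_genes = ds.counts_xa.shape
    if len(ds.cells) != n_cells:
        report.append(
            f"dimension mismatch: {len(ds.cells)} cell rows for {n_cells} matrix rows"
        )
    if len(ds.genes) != n_genes:
        report.append(
            f"dimension mismatch: {len(ds.genes)} gene rows for {n_genes} matrix columns"
        )

    for name, mat in (("xa_strain", ds.counts_xa), ("xi_strain", ds.counts_xi)):
        if mat.nnz and mat.data.min() < 0:
            coo = mat.tocoo()
            bad = np.flatnonzero(coo.data < 0)[0]
            report.append(
                f"negative count in {name} at cell {coo.row[bad]}, gene {coo.col[bad]}"
            )

    missing_cell_cols = [c for c in CELL_COLUMNS if c not in ds.cells.columns]
    if missing_cell_cols:
        report.append(f"cell metadata missing columns: {missing_cell_cols}")
    missing_gene_cols = [c for c in GENE_COLUMNS if c not in ds.genes.columns]
    if missing_gene_cols:
        report.append(f"gene annotation missing columns: {missing_gene_cols}")
    if missing_cell_cols or missing_gene_cols:
        return report

    dup = ds.cells["barcode"].duplicated()
    if dup.any():
        report.append(f"duplicate barcode at row {int(np.flatnonzero(dup)[0])}")
    dup = ds.genes["gene_id"].duplicated()
    if dup.any():
        report.append(f"duplicate gene_id at row {int(np.flatnonzero(dup)[0])}")

    for col in CELL_COLUMNS:
        empty = ds.cells[col].isna() | (ds.cells[col].astype(str) == "")
        if empty.any():
            report.append(f"empty {col} at cell row {int(np.flatnonzero(empty)[0])}")
    bad_age = ~ds.cells["age_group"].isin(AGE_GROUPS)
    if bad_age.any():
        report.append(
            f"unknown age_group at cell row {int(np.flatnonzero(bad_age)[0])} "
            f"(expected one of {AGE_GROUPS})"
        )
    ages_per_sample = ds.cells.groupby("sample_id", observed=True)["age_group"].nunique()
    for sample_id, n in ages_per_sample.items():
        if n > 1:
            report.append(f"sample/age inconsistency: sample {sample_id!r} maps to {n} age groups")

    empty_chrom = ds.genes["chromosome"].isna() | (ds.genes["chromosome"].astype(str) == "")
    if empty_chrom.any():
        report.append(
            f"empty chromosome at gene row {int(np.flatnonzero(empty_chrom)[0])}"
        )
    if n_genes:
        chrom = ds.genes["chromosome"].astype(str)
        if not (chrom == "X").any():
            report.append("no X-linked gene present")
        if not (chrom != "X").any():
            report.append("no autosomal gene present")
    return report


def _write_matrix(path: Path, mat: sp.spmatrix) -> None:
    # Stored genes x cells; a comment line records the orientation so the
    # reader can normalize it.
    coo = mat.T.tocoo()
    coo.sum_duplicates()
    buf = io.BytesIO()
    scipy.io.mmwrite(
        buf, coo, comment=_ORIENTATION_GENES_CELLS, field="integer"
    )
    path.write_bytes(buf.getvalue())


def _read_orientation(path: Path) -> str:
    with open(path) as fh:
        for line in fh:
            if not line.startswith("%"):
                break
            stripped = line.lstrip("%").strip().lower()
            if stripped.startswith("orientation:"):
                return stripped
    return _ORIENTATION_GENES_CELLS


def write_dataset(ds: AlleleCountDataset, bundle_path: str | Path) -> None:
    """Write a dataset bundle; deterministic byte-for-byte for a given dataset."""
    bundle = Path(bundle_path)
    bundle.mkdir(parents=True, exist_ok=True)
    _write_matrix(bundle / XA_MATRIX, ds.counts_xa)
    _write_matrix(bundle / XI_MATRIX, ds.counts_xi)
    ds.cells[CELL_COLUMNS].to_csv(bundle / CELLS_TSV, sep="\t", index=False)
    ds.genes[GENE_COLUMNS].to_csv(bundle / GENES_TSV, sep="\t", index=False)


def read_allele_dataset(bundle_path: str | Path) -> AlleleCountDataset:
    """Read and validate a dataset bundle written by :func:`write_dataset`.

    Raises
    ------
    MissingComponentError
        if any of the four bundle files is absent.
    InconsistentBundleError
        if matrix dimensions disagree with each other or the sidecars.
    """
    bundle = Path(bundle_path)
    for name in (XA_MATRIX, XI_MATRIX, CELLS_TSV, GENES_TSV):
        if not (bundle / name).is_file():
            raise MissingComponentError(f"missing component: {name} in {bundle}")

    mats = {}
    for name in (XA_MATRIX, XI_MATRIX):
        mat = scipy.io.mmread(bundle / name)
        if _read_orientation(bundle / name) == _ORIENTATION_GENES_CELLS:
            mat = mat.T
        mats[name] = sp.csr_matrix(mat, dtype=np.int64)

    if mats[XA_MATRIX].shape != mats[XI_MATRIX].shape:
        raise InconsistentBundleError(
            f"inconsistent bundle: {XA_MATRIX} is {mats[XA_MATRIX].shape} "
            f"but {XI_MATRIX} is {mats[XI_MATRIX].shape}"
        )

    cells = pd.read_csv(bundle / CELLS_TSV, sep="\t", dtype=str).fillna("")
    genes = pd.read_csv(bundle / GENES_TSV, sep="\t", dtype=str).fillna("")
    n_cells, n_genes = mats[XA_MATRIX].shape
    if len(cells) != n_cells or len(genes) != n_genes:
        raise InconsistentBundleError(
            f"inconsistent bundle: matrices are {n_cells} cells x {n_genes} genes "
            f"but sidecars have {len(cells)} cells and {len(genes)} genes"
        )
    return AlleleCountDataset(mats[XA_MATRIX], mats[XI_MATRIX], cells, genes)
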