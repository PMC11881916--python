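"""Per-cell normalization and allele-resolved pseudobulk aggregation.

Escape calling pools normalized reads across samples within
(cell type x age); differential expression needs raw integer sums per
(cell type x sample); the combined-cell analysis pools by age only.
Normalization uses one factor per cell shared by both allele matrices, the
only choice that preserves within-cell allelic ratios.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .dataset import AlleleCountDataset

logger = logging.getLogger(__name__)

#: Grouping schemes -> cell-metadata columns forming the group key.
GROUPINGS = {
    "celltype_age": ("cell_type", "age_group"),
    "celltype_sample": ("cell_type", "sample_id"),
    "age": ("age_group",),
}

ALLELES = ("xa_strain", "xi_strain")


class EmptyDatasetError(ValueError):
    """Every cell has zero allele-assigned reads."""


@dataclass
class PseudobulkTable:
    """Dense per-group allele read sums, zero-filled over all (gene, group).

    ``xa``/``xi`` are n_groups x n_genes arrays; ``groups`` has one row per
    group with the key columns of the scheme, in sorted key order.
    """

    scheme: str
    groups: pd.DataFrame
    gene_ids: np.ndarray
    chromosomes: np.ndarray
    xa: np.ndarray
    xi: np.ndarray

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    def x_mask(self) -> np.ndarray:
        return self.chromosomes == "X"

    def group_labels(self) -> list[tuple]:
        return [tuple(row) for row in self.groups.itertuples(index=False)]

    def to_long(self) -> pd.DataFrame:
        """Long format: gene_id, allele, group key columns, value."""
        frames = []
        key_cols = list(self.groups.columns)
        for allele, values in (("xa_strain", self.xa), ("xi_strain", self.xi)):
            for gi in range(self.n_groups):
                frame = pd.DataFrame(
                    {
                        "gene_id": self.gene_ids,
                        "allele": allele,
                        "value": values[gi],
                    }
                )
                for col in key_cols:
                    frame[col] = self.groups.iloc[gi][col]
                frames.append(frame[["gene_id", "allele", *key_cols, "value"]])
        return pd.concat(frames, ignore_index=True)


def normalize_cells(ds: AlleleCountDataset, target_sum: float = 1e4) -> np.ndarray:
    """Per-cell scale factors ``target_sum / combined_total``.

    The combined total sums both allele matrices, and the one factor applies
    to both, so within-cell allelic ratios are unchanged.  Cells with zero
    combined total get a NaN factor and are dropped (with a logged warning)
    by aggregation.
    """
    totals = np.asarray(ds.counts_xa.sum(axis=1)).ravel() + np.asarray(
        ds.counts_xi.sum(axis=1)
    ).ravel()
    if ds.n_cells == 0 or not (totals > 0).any():
        raise EmptyDatasetError("empty dataset: no cell has allele-assigned reads")
    n_zero = int((totals == 0).sum())
    if n_zero:
        logger.warning("dropping %d cells with zero allele-assigned reads", n_zero)
    with np.errstate(divide="ignore"):
        factors = np.where(totals > 0, target_sum / np.maximum(totals, 1), np.nan)
    return factors


def _group_structure(ds: AlleleCountDataset, scheme: str) -> tuple[pd.DataFrame, np.ndarray]:
    if scheme not in GROUPINGS:
        raise ValueError(f"unknown grouping scheme {scheme!r}; expected one of {sorted(GROUPINGS)}")
    key_cols = list(GROUPINGS[scheme])
    keys = ds.cells[key_cols].astype(str)
    groups = keys.drop_duplicates().sort_values(key_cols, kind="mergesort").reset_index(drop=True)
    lookup = {tuple(row): i for i, row in enumerate(groups.itertuples(index=False))}
    codes = np.array([lookup[tuple(row)] for row in keys.itertuples(index=False)])
    return groups, codes


def _weighted_group_sums(
    mat: sp.spmatrix, codes: np.ndarray, n_groups: int, weights: np.ndarray
) -> np.ndarray:
    indicator = sp.csr_matrix(
        (weights, (codes, np.arange(len(codes)))), shape=(n_groups, len(codes))
    )
    return np.asarray((indicator @ mat).todense())


def aggregate(
    ds: AlleleCountDataset, factors: np.ndarray, scheme: str
) -> PseudobulkTable:
    """Sum factor-scaled counts per group: value = sum_c factor_c * count_c.

    Cells with NaN factors are excluded.  Absent (gene, group) combinations
    are zero-filled by construction.
    """
    groups, codes = _group_structure(ds, scheme)
    weights = np.where(np.isfinite(factors), factors, 0.0)
    xa = _weighted_group_sums(ds.counts_xa, codes, len(groups), weights)
    xi = _weighted_group_sums(ds.counts_xi, codes, len(groups), weights)
    return PseudobulkTable(
        scheme=scheme,
        groups=groups,
        gene_ids=ds.genes["gene_id"].to_numpy(),
        chromosomes=ds.genes["chromosome"].to_numpy(),
        xa=xa,
        xi=xi,
    )


def integer_pseudobulk(ds: AlleleCountDataset, scheme: str) -> PseudobulkTable:
    """Raw integer sums per group, for count-model differential expression."""
    groups, codes = _group_structure(ds, scheme)
    ones = np.ones(ds.n_cells)
    xa = _weighted_group_sums(ds.counts_xa, codes, len(groups), ones)
    xi = _weighted_group_sums(ds.counts_xi, codes, len(groups), ones)
    return PseudobulkTable(
        scheme=scheme,
        groups=groups,
        gene_ids=ds.genes["gene_id"].to_numpy(),
        chromosomes=ds.genes["chromosome"].to_numpy(),
        xa=np.asarray(xa, dtype=np.int64),
        xi=np.asarray(xi, dtype=np.int64),
    )
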