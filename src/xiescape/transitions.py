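"""Aging transitions of escape status, Sankey summaries, and Xi-only views.

A gene's young and old escape calls within one cell type combine into one
of six categories: ``increased`` (escapee at both ages with the old CI
lower bound strictly above the young CI upper bound), ``maintained``
(escapee at both ages, CIs overlapping), ``lost`` (escapee young, inactive
old), ``new_escape`` (inactive young, escapee old), ``inactive_both``, and
``not_assessable`` (either age not assessable or not detected; low-Xa genes
propagate, they are never folded into inactive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats

from .dataset import AlleleCountDataset
from .escape import (
    STATUS_ESCAPEE,
    STATUS_INACTIVE,
    STATUS_NOT_ASSESSABLE,
    STATUS_NOT_DETECTED,
)

CATEGORIES = (
    "increased",
    "maintained",
    "lost",
    "new_escape",
    "inactive_both",
    "not_assessable",
)

#: Categories carrying age information (used for cross-cell-type patterns).
INFORMATIVE_CATEGORIES = ("increased", "maintained", "lost", "new_escape")


class UninformativeError(ValueError):
    """No informative category among a gene's records."""


class DegenerateTestError(ValueError):
    """Paired test undefined: fewer than two pairs or zero-variance differences."""


def classify_transition(young, old) -> str:
    """Category for one (gene, cell type) from its young and old calls.

    ``young`` and ``old`` are any objects with ``gene_id``, ``cell_type``,
    ``status``, ``ci_lower`` and ``ci_upper`` attributes (e.g. dataframe
    row tuples or :class:`~xiescape.escape.EscapeCall`).
    """
    if young.gene_id != old.gene_id or young.cell_type != old.cell_type:
        raise ValueError(
            f"call mismatch: young is ({young.gene_id}, {young.cell_type}), "
            f"old is ({old.gene_id}, {old.cell_type})"
        )
    uncallable = (STATUS_NOT_ASSESSABLE, STATUS_NOT_DETECTED)
    if young.status in uncallable or old.status in uncallable:
        return "not_assessable"
    if young.status == STATUS_ESCAPEE and old.status == STATUS_ESCAPEE:
        return "increased" if old.ci_lower > young.ci_upper else "maintained"
    if young.status == STATUS_ESCAPEE:
        return "lost"
    if old.status == STATUS_ESCAPEE:
        return "new_escape"
    return "inactive_both"


def classify_transitions_table(calls: pd.DataFrame) -> pd.DataFrame:
    """One transition record per (gene, cell type) from an escape-call table.

    ``calls`` is the output of :func:`xiescape.escape.call_escape_table`
    and must contain both ages for every (gene, cell type).
    """
    young = calls[calls["age_group"] == "young"].set_index(["gene_id", "cell_type"])
    old = calls[calls["age_group"] == "old"].set_index(["gene_id", "cell_type"])
    if not young.index.equals(old.index):
        missing = young.index.symmetric_difference(old.index)
        raise ValueError(f"ages do not cover the same (gene, cell type) pairs: {list(missing)[:5]}")

    records = []
    for key in young.index:
        y = young.loc[key]
        o = old.loc[key]
        s_y, s_o = y["status"], o["status"]
        if s_y in (STATUS_NOT_ASSESSABLE, STATUS_NOT_DETECTED) or s_o in (
            STATUS_NOT_ASSESSABLE,
            STATUS_NOT_DETECTED,
        ):
            category = "not_assessable"
        elif s_y == STATUS_ESCAPEE and s_o == STATUS_ESCAPEE:
            category = "increased" if o["ci_lower"] > y["ci_upper"] else "maintained"
        elif s_y == STATUS_ESCAPEE:
            category = "lost"
        elif s_o == STATUS_ESCAPEE:
            category = "new_escape"
        else:
            category = "inactive_both"
        records.append(
            {
                "gene_id": key[0],
                "cell_type": key[1],
                "young_status": s_y,
                "old_status": s_o,
                "young_p_escadj": y["p_escadj"],
                "old_p_escadj": o["p_escadj"],
                "young_ci_lower": y["ci_lower"],
                "young_ci_upper": y["ci_upper"],
                "old_ci_lower": o["ci_lower"],
                "old_ci_upper": o["ci_upper"],
                "detected": bool(
                    (y["xi_reads"] + y["xa_reads"] > 0)
                    or (o["xi_reads"] + o["xa_reads"] > 0)
                ),
                "category": category,
            }
        )
    return pd.DataFrame.from_records(records)


@dataclass
class SankeySummary:
    """Per-cell-type category counts plus detected-gene totals."""

    counts: pd.DataFrame  # index cell_type, one column per category
    n_detected: pd.Series  # per cell_type
    n_genes: pd.Series  # per cell_type, all X genes considered

    def conserved(self) -> bool:
        return bool((self.counts.sum(axis=1) == self.n_genes).all())


def summarize_sankey(records: pd.DataFrame) -> SankeySummary:
    """Exact category counts per cell type; errors on duplicate records."""
    dup = records.duplicated(subset=["gene_id", "cell_type"])
    if dup.any():
        first = records.loc[dup.idxmax()]
        raise ValueError(
            f"duplicate transition record for ({first['gene_id']}, {first['cell_type']})"
        )
    counts = (
        records.pivot_table(
            index="cell_type", columns="category", values="gene_id", aggfunc="count", fill_value=0
        )
        .reindex(columns=list(CATEGORIES), fill_value=0)
        .astype(int)
    )
    counts.columns.name = None
    n_detected = records.groupby("cell_type")["detected"].sum().astype(int)
    n_genes = records.groupby("cell_type")["gene_id"].count()
    return SankeySummary(counts=counts, n_detected=n_detected, n_genes=n_genes)


def cross_celltype_pattern(categories) -> str:
    """``consistent:<category>`` or ``mixed`` over one gene's cell types.

    Only informative categories count; ``inactive_both`` and
    ``not_assessable`` records are ignored.  Raises
    :class:`UninformativeError` when nothing informative remains.
    """
    informative = [c for c in categories if c in INFORMATIVE_CATEGORIES]
    if not informative:
        raise UninformativeError("no informative escape category across cell types")
    unique = sorted(set(informative))
    if len(unique) == 1:
        return f"consistent:{unique[0]}"
    return "mixed"


def cross_celltype_table(records: pd.DataFrame) -> pd.DataFrame:
    """Per-gene pattern across cell types; uninformative genes are skipped."""
    rows = []
    for gene_id, sub in records.groupby("gene_id"):
        try:
            pattern = cross_celltype_pattern(sub["category"])
        except UninformativeError:
            continue
        n_informative = int(sub["category"].isin(INFORMATIVE_CATEGORIES).sum())
        rows.append(
            {"gene_id": gene_id, "pattern": pattern, "n_informative_cell_types": n_informative}
        )
    return pd.DataFrame(rows, columns=["gene_id", "pattern", "n_informative_cell_types"])


def xi_dotplot_stats(
    ds: AlleleCountDataset,
    factors: np.ndarray,
    genes: list[str],
    groups: tuple[str, ...] = ("cell_type", "age_group"),
) -> pd.DataFrame:
    """Dot-plot statistics of inactive-strain expression.

    Per (gene, group): the fraction of the group's cells with a nonzero
    inactive-strain count, and the mean over all group cells of
    log(1 + normalized inactive-strain count).
    """
    gene_pos = {g: i for i, g in enumerate(ds.genes["gene_id"])}
    unknown = [g for g in genes if g not in gene_pos]
    if unknown:
        raise ValueError(f"unknown genes: {unknown[:5]}")
    cols = [gene_pos[g] for g in genes]
    xi = np.asarray(ds.counts_xi[:, cols].todense(), dtype=float)
    keep = np.isfinite(factors)
    xi_norm = np.log1p(xi * np.where(keep, factors, 0.0)[:, None])

    keys = ds.cells[list(groups)].astype(str)
    rows = []
    for label, idx in keys.groupby(list(groups), sort=True).groups.items():
        members = np.asarray([i for i in idx if keep[i]])
        if members.size == 0:
            raise ValueError(f"empty group {label} after dropping zero-count cells")
        frac = (xi[members] > 0).mean(axis=0)
        mean_expr = xi_norm[members].mean(axis=0)
        frame = pd.DataFrame(
            {
                "gene_id": genes,
                "fraction_expressing": frac,
                "mean_xi_expression": mean_expr,
            }
        )
        label = (label,) if not isinstance(label, tuple) else label
        for col, value in zip(groups, label):
            frame[col] = value
        rows.append(frame[["gene_id", *groups, "mean_xi_expression", "fraction_expressing"]])
    return pd.concat(rows, ignore_index=True)


def paired_escape_change_test(pairs) -> tuple[float, float, int]:
    """Paired two-tailed t test on (young, old) corrected escape values.

    Returns (t statistic, two-sided p, n).  Raises
    :class:`DegenerateTestError` for n < 2 or zero-variance differences.
    """
    arr = np.asarray(list(pairs), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise DegenerateTestError(f"need >= 2 (young, old) pairs, got shape {arr.shape}")
    young, old = arr[:, 0], arr[:, 1]
    diffs = old - young
    if np.allclose(diffs.std(ddof=1), 0.0):
        raise DegenerateTestError("zero variance of paired differences")
    result = scipy.stats.ttest_rel(old, young)
    return float(result.statistic), float(result.pvalue), arr.shape[0]
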