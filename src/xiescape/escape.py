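"""Escape quantification: proportion, mapping-bias correction, 99% CI, status.

For each X-linked gene in a (cell type, age) context with normalized
allele-assigned read sums Xi (inactive-X strain) and Xa (active-X strain):

    P_esc    = Xi / (Xi + Xa)
    P_escadj = P_esc / (P_esc + r * (1 - P_esc)),  r = A_Tcast / A_Tmus
    99% CI   = P_escadj +/- 2.575 * sqrt(P_escadj * (1 - P_escadj) / (Xi + Xa))

where r is the genome-wide autosomal alternate/reference strain read ratio
(the mapping-bias estimate, computed once globally over all cells).  A gene
is called an escapee when the CI lower bound is strictly greater than 0,
the corrected proportion strictly exceeds 0.05, and both Xi and Xa reach
the 5th percentile of the pooled X-linked allelic read distribution.  A
gene whose Xa falls below that depth threshold is not assessable (escape
trends are not calculated for it); one with no reads at all is not
detected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pseudobulk import PseudobulkTable

#: CI multiplier as printed in the interval formula (not the rounder 2.5758).
Z_99 = 2.575
#: Minimum corrected escape proportion for escapee status (strict).
ESCAPE_MIN = 0.05
#: Percentile of the pooled X allelic read distribution used as depth floor.
DEPTH_PERCENTILE = 5.0

STATUS_ESCAPEE = "escapee"
STATUS_INACTIVE = "inactive"
STATUS_NOT_ASSESSABLE = "not_assessable"
STATUS_NOT_DETECTED = "not_detected"


class NotDetectedError(ValueError):
    """Both allele read sums are zero; no proportion exists."""


@dataclass(frozen=True)
class BiasRatio:
    """Genome-wide autosomal strain read totals and their ratio."""

    a_t_cast: float
    a_t_mus: float

    @property
    def ratio(self) -> float:
        return self.a_t_cast / self.a_t_mus


@dataclass
class EscapeCall:
    gene_id: str
    cell_type: str
    age_group: str
    xi_reads: float
    xa_reads: float
    p_esc: float
    p_escadj: float
    ci_lower: float
    ci_upper: float
    status: str


def escape_proportion(xi_reads: float, xa_reads: float) -> float:
    """Proportion of inactive-strain reads among all assigned reads."""
    total = xi_reads + xa_reads
    if total <= 0:
        raise NotDetectedError("no allele-assigned reads: escape proportion undefined")
    return xi_reads / total


def autosomal_bias_ratio(pb: PseudobulkTable) -> BiasRatio:
    """Mapping-bias ratio from genome-wide autosomal strain totals.

    Sums normalized reads over every autosomal gene and every group of the
    table (the global estimate, not per cell type).
    """
    autosomal = ~pb.x_mask()
    if not autosomal.any():
        raise ValueError("no autosomal genes: cannot estimate mapping bias")
    a_t_mus = float(pb.xa[:, autosomal].sum())
    a_t_cast = float(pb.xi[:, autosomal].sum())
    if a_t_mus <= 0:
        raise ValueError("zero reference-strain autosomal reads: bias ratio undefined")
    return BiasRatio(a_t_cast=a_t_cast, a_t_mus=a_t_mus)


def adjust_escape(p_esc: float, ratio: float | BiasRatio) -> float:
    """Mapping-bias-corrected escape proportion."""
    r = ratio.ratio if isinstance(ratio, BiasRatio) else float(ratio)
    if not 0.0 <= p_esc <= 1.0:
        raise ValueError(f"p_esc must be in [0, 1], got {p_esc}")
    denom = p_esc + r * (1.0 - p_esc)
    if denom == 0.0:
        return 0.0
    return p_esc / denom


def escape_interval(p_escadj: float, total_reads: float) -> tuple[float, float]:
    """99% Wald interval on the corrected proportion, clamped to [0, 1]."""
    if total_reads <= 0:
        raise ValueError(f"total_reads must be positive, got {total_reads}")
    half = Z_99 * np.sqrt(p_escadj * (1.0 - p_escadj) / total_reads)
    return (max(0.0, p_escadj - half), min(1.0, p_escadj + half))


def depth_thresholds(pb: PseudobulkTable, percentile: float = DEPTH_PERCENTILE) -> float:
    """Depth floor: a percentile of the pooled X allelic read distribution.

    Pools the per-(gene, allele, group) X-linked read sums of the given
    table into one distribution and takes the linear-interpolation
    percentile.  Recomputed per analysis level, so scaling all normalized
    reads rescales the threshold identically (status is scale-invariant).
    """
    x = pb.x_mask()
    if not x.any():
        raise ValueError("no X-linked genes: depth threshold undefined")
    pooled = np.concatenate([pb.xa[:, x].ravel(), pb.xi[:, x].ravel()])
    return float(np.percentile(pooled, percentile))


def call_escape_status(
    xi_reads: float,
    xa_reads: float,
    p_escadj: float,
    ci_lower: float,
    threshold: float,
    escape_min: float = ESCAPE_MIN,
) -> str:
    """Escapee / inactive / not_assessable / not_detected for one gene-context.

    Thresholds are strict exactly as stated: CI lower bound > 0, corrected
    proportion > ``escape_min``; depth ties at the threshold pass ("lower
    than" is strict).
    """
    if xi_reads + xa_reads <= 0:
        return STATUS_NOT_DETECTED
    if xa_reads < threshold:
        return STATUS_NOT_ASSESSABLE
    if (
        ci_lower > 0.0
        and p_escadj > escape_min
        and xi_reads >= threshold
        and xa_reads >= threshold
    ):
        return STATUS_ESCAPEE
    return STATUS_INACTIVE


def call_escape_table(
    pb: PseudobulkTable,
    ratio: BiasRatio | float,
    threshold: float | None = None,
    escape_min: float = ESCAPE_MIN,
    z: float = Z_99,
    depth_percentile: float = DEPTH_PERCENTILE,
) -> pd.DataFrame:
    """Escape calls for every X-linked gene in every group of ``pb``.

    ``pb`` must be grouped by (cell_type, age_group) or by (age_group,);
    in the latter case the combined analysis is reported with cell type
    ``"all"``.  If ``threshold`` is None it is computed from ``pb`` itself
    via :func:`depth_thresholds`.
    """
    if pb.scheme not in ("celltype_age", "age"):
        raise ValueError(f"escape calling needs a celltype_age or age table, got {pb.scheme!r}")
    r = ratio.ratio if isinstance(ratio, BiasRatio) else float(ratio)
    if threshold is None:
        threshold = depth_thresholds(pb, depth_percentile)

    x = pb.x_mask()
    gene_ids = pb.gene_ids[x]
    rows = []
    for gi, label in enumerate(pb.group_labels()):
        if pb.scheme == "celltype_age":
            cell_type, age_group = label
        else:
            (age_group,) = label
            cell_type = "all"
        xa = pb.xa[gi, x]
        xi = pb.xi[gi, x]
        total = xa + xi
        with np.errstate(invalid="ignore", divide="ignore"):
            p_esc = np.where(total > 0, xi / np.maximum(total, 1e-300), np.nan)
            denom = p_esc + r * (1.0 - p_esc)
            p_adj = np.where(denom > 0, p_esc / np.maximum(denom, 1e-300), 0.0)
            p_adj = np.where(np.isnan(p_esc), np.nan, p_adj)
            half = z * np.sqrt(p_adj * (1.0 - p_adj) / total)
        ci_lower = np.maximum(0.0, p_adj - half)
        ci_upper = np.minimum(1.0, p_adj + half)
        status = [
            call_escape_status(xi[k], xa[k], p_adj[k], ci_lower[k], threshold, escape_min)
            for k in range(len(gene_ids))
        ]
        rows.append(
            pd.DataFrame(
                {
                    "gene_id": gene_ids,
                    "cell_type": cell_type,
                    "age_group": age_group,
                    "xi_reads": xi,
                    "xa_reads": xa,
                    "p_esc": p_esc,
                    "p_escadj": p_adj,
                    "ci_lower": ci_lower,
                    "ci_upper": ci_upper,
                    "status": status,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
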