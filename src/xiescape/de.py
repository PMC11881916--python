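"""Pseudobulk allele-level differential expression and chromosome enrichment.

Features are (gene, allele) pairs throughout — the allele-resolved design
doubles the features, and the active- and inactive-strain counts of one
gene are tested separately.  The engine is a negative-binomial GLM with a
Wald test on the age coefficient:

* size factors: median-of-ratios over features positive in all samples,
  falling back to library totals when no such feature exists;
* gene-wise dispersion: method-of-moments on size-factor-normalized counts
  within age groups, floored at 1e-8;
* per-feature IRLS fit of ``log mu = log s_j + b0 + b1 * old_j``, Wald
  z = b1 / se(b1), two-sided normal p, Benjamini-Hochberg adjustment over
  the features tested within one analysis.

A feature is significant when the adjusted p is strictly below 0.05 and
the log2 fold change is strictly outside [-0.1, 0.1].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.stats
from statsmodels.stats.multitest import multipletests

from .pseudobulk import PseudobulkTable

DE_ALPHA = 0.05
DE_LFC = 0.1
MIN_TOTAL_READS = 10
MIN_SINGLE_SAMPLE = 10
_DISPERSION_FLOOR = 1e-8

#: Hippocampal cell classes used for DEG category calls.
DEFAULT_CELL_CLASS_MAP = {
    "CA1": "neuronal",
    "CA3": "neuronal",
    "DG": "neuronal",
    "Glut_Undef": "neuronal",
    "GABA": "neuronal",
    "Astro": "glial",
    "MG": "glial",
    "Oligo": "glial",
    "OPC": "glial",
}

CATEGORY_ORDER = ("neuronal", "glial", "multiple", "cell_type_specific", "excluded_discordant")


@dataclass
class EnrichmentResult:
    focal: str
    comparison: str
    n_sig_focal: int
    n_expressed_focal: int
    n_sig_comparison: int
    n_expressed_comparison: int
    chi2: float
    p_value: float


@dataclass
class CategoryAssignment:
    gene_id: str
    allele: str
    category: str
    supporting: dict  # cell type -> direction (+1 up in old, -1 down)


def filter_de_genes(
    counts: np.ndarray,
    min_total: int = MIN_TOTAL_READS,
    min_single: int = MIN_SINGLE_SAMPLE,
    require_every_sample: bool = False,
) -> np.ndarray:
    """Boolean mask of retained features (rows of a features x samples array).

    Default reading of the depth filter: total across samples >= 10 AND at
    least one individual sample >= 10.  ``require_every_sample`` switches
    the second clause to every sample.
    """
    counts = np.asarray(counts)
    totals = counts.sum(axis=1)
    if require_every_sample:
        single = counts.min(axis=1) >= min_single
    else:
        single = counts.max(axis=1) >= min_single
    return (totals >= min_total) & single


def _size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors with library-total fallback."""
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive].astype(float))
        logratio = logc - logc.mean(axis=1, keepdims=True)
        return np.exp(np.median(logratio, axis=0))
    totals = counts.sum(axis=0).astype(float)
    if not (totals > 0).all():
        raise ValueError("cannot compute size factors: a sample has zero total counts")
    return totals / np.exp(np.mean(np.log(totals)))


def _mom_dispersion(counts: np.ndarray, sf: np.ndarray, is_old: np.ndarray) -> np.ndarray:
    """Method-of-moments NB dispersion per feature, floored at 1e-8."""
    q = counts / sf[None, :]
    alphas = np.zeros(counts.shape[0])
    weight = 0.0
    for mask in (~is_old, is_old):
        n = int(mask.sum())
        if n < 2:
            continue
        qg = q[:, mask]
        mean = qg.mean(axis=1)
        var = qg.var(axis=1, ddof=1)
        # Poisson contribution on the normalized scale is mean * E[1/s].
        poisson = mean * np.mean(1.0 / sf[mask])
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mean > 0, (var - poisson) / np.maximum(mean, 1e-300) ** 2, 0.0)
        alphas += np.nan_to_num(a) * (n - 1)
        weight += n - 1
    if weight > 0:
        alphas /= weight
    return np.maximum(alphas, _DISPERSION_FLOOR)


def _nb_wald(
    counts: np.ndarray, sf: np.ndarray, is_old: np.ndarray, alpha: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized IRLS NB-GLM fit; returns (log2fc, wald z, p)."""
    n_feat, n_samp = counts.shape
    x = np.column_stack([np.ones(n_samp), is_old.astype(float)])  # shared design
    offset = np.log(sf)

    # Initialize from normalized group means (pseudocount keeps logs finite).
    q = counts / sf[None, :]
    mean_young = q[:, ~is_old].mean(axis=1)
    mean_old = q[:, is_old].mean(axis=1)
    eps = 1e-8
    b0 = np.log(mean_young + eps)
    b1 = np.log(mean_old + eps) - b0
    beta = np.column_stack([b0, b1])

    for _ in range(60):
        eta = offset[None, :] + beta @ x.T
        eta = np.clip(eta, -50.0, 50.0)
        mu = np.exp(eta)
        w = mu / (1.0 + alpha[:, None] * mu)
        z = eta - offset[None, :] + (counts - mu) / np.maximum(mu, 1e-300)
        xtwx = np.einsum("fs,st,su->ftu", w, x, x)
        xtwz = np.einsum("fs,st,fs->ft", w, x, z)
        xtwx += 1e-10 * np.eye(2)[None, :, :]
        new_beta = np.linalg.solve(xtwx, xtwz[:, :, None])[:, :, 0]
        new_beta = np.clip(new_beta, -30.0, 30.0)
        delta = np.abs(new_beta - beta).max()
        beta = new_beta
        if delta < 1e-10:
            break

    eta = np.clip(offset[None, :] + beta @ x.T, -50.0, 50.0)
    mu = np.exp(eta)
    w = mu / (1.0 + alpha[:, None] * mu)
    xtwx = np.einsum("fs,st,su->ftu", w, x, x) + 1e-10 * np.eye(2)[None, :, :]
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.maximum(cov[:, 1, 1], 1e-300))
    wald = beta[:, 1] / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(wald))
    log2fc = beta[:, 1] / np.log(2.0)
    return log2fc, wald, p


def fit_pseudobulk_de(
    counts: np.ndarray,
    age_groups,
    feature_ids: list[tuple[str, str]],
    alpha: float = DE_ALPHA,
    lfc: float = DE_LFC,
) -> pd.DataFrame:
    """NB-Wald differential expression, old versus young, per feature.

    ``counts`` is features x samples integer pseudobulk, ``age_groups`` the
    per-sample age labels, ``feature_ids`` the (gene_id, allele) per row.
    Returns a record per feature with log2fc (old vs young), p, BH-adjusted
    p, and the significance flag.
    """
    counts = np.asarray(counts, dtype=float)
    ages = np.asarray(age_groups)
    is_old = ages == "old"
    if is_old.all() or (~is_old).all():
        raise ValueError("degenerate design: both age groups are required")
    if is_old.sum() < 2 or (~is_old).sum() < 2:
        raise ValueError("need at least 2 samples per age group")
    if counts.shape[0] == 0:
        return pd.DataFrame(
            columns=["gene_id", "allele", "log2fc", "p_value", "p_adjusted", "significant"]
        )

    sf = _size_factors(counts)
    disp = _mom_dispersion(counts, sf, is_old)
    log2fc, wald, p = _nb_wald(counts, sf, is_old, disp)
    p_adj = multipletests(p, method="fdr_bh")[1]
    records = pd.DataFrame(
        {
            "gene_id": [f[0] for f in feature_ids],
            "allele": [f[1] for f in feature_ids],
            "log2fc": log2fc,
            "wald_stat": wald,
            "p_value": p,
            "p_adjusted": p_adj,
        }
    )
    records["significant"] = call_significant(records, alpha=alpha, lfc=lfc)
    return records


def call_significant(
    records: pd.DataFrame, alpha: float = DE_ALPHA, lfc: float = DE_LFC
) -> np.ndarray:
    """Strict thresholds exactly as printed: p_adj < alpha and |log2fc| > lfc."""
    return (
        (records["p_adjusted"].to_numpy() < alpha)
        & (np.abs(records["log2fc"].to_numpy()) > lfc)
    )


def run_de_for_cell_type(
    pb_ct_sample: PseudobulkTable,
    cell_type: str,
    sample_ages: dict[str, str],
    alpha: float = DE_ALPHA,
    lfc: float = DE_LFC,
) -> pd.DataFrame:
    """Filter and fit DE for one cell type (or ``"all"`` pooled over types)."""
    labels = pb_ct_sample.group_labels()
    if cell_type == "all":
        keep = list(range(len(labels)))
        sample_of = [lab[1] for lab in labels]
        samples = sorted(set(sample_of))
        xa = np.zeros((len(samples), pb_ct_sample.xa.shape[1]))
        xi = np.zeros_like(xa)
        for gi, s in enumerate(sample_of):
            si = samples.index(s)
            xa[si] += pb_ct_sample.xa[gi]
            xi[si] += pb_ct_sample.xi[gi]
    else:
        keep = [i for i, lab in enumerate(labels) if lab[0] == cell_type]
        if not keep:
            raise ValueError(f"no pseudobulk groups for cell type {cell_type!r}")
        samples = [labels[i][1] for i in keep]
        xa = pb_ct_sample.xa[keep]
        xi = pb_ct_sample.xi[keep]

    ages = [sample_ages[s] for s in samples]
    counts = np.vstack([xa.T, xi.T])
    features = [(g, "xa_strain") for g in pb_ct_sample.gene_ids] + [
        (g, "xi_strain") for g in pb_ct_sample.gene_ids
    ]
    mask = filter_de_genes(counts)
    records = fit_pseudobulk_de(
        counts[mask],
        ages,
        [features[i] for i in np.flatnonzero(mask)],
        alpha=alpha,
        lfc=lfc,
    )
    records.insert(2, "cell_type", cell_type)
    return records


def chromosome_enrichment(
    sig_features,
    expressed_features,
    gene_chromosomes: dict[str, str],
    focal: str = "X",
    comparison: str = "autosomes",
) -> EnrichmentResult:
    """Pearson chi-square (1 df, no continuity correction) on the 2x2 table
    [significant vs not] x [focal chromosome vs comparison set].

    Features may be (gene_id, allele) pairs or bare gene ids; significant
    DEG counts are normalized to the expressed features of each side.
    """

    def gene_of(feature):
        return feature[0] if isinstance(feature, tuple) else feature

    def on_focal(chrom):
        return chrom == focal

    def on_comparison(chrom):
        if comparison == "autosomes":
            return chrom != focal
        return chrom == comparison

    sig = set(sig_features)
    expressed = list(expressed_features)
    expressed_set = set(expressed)
    missing = [f for f in sig if f not in expressed_set]
    if missing:
        raise ValueError(f"significant features absent from expressed set: {missing[:5]}")

    n_sig_f = n_expr_f = n_sig_c = n_expr_c = 0
    for f in expressed:
        chrom = gene_chromosomes[gene_of(f)]
        if on_focal(chrom):
            n_expr_f += 1
            n_sig_f += f in sig
        elif on_comparison(chrom):
            n_expr_c += 1
            n_sig_c += f in sig
    table = np.array(
        [[n_sig_f, n_expr_f - n_sig_f], [n_sig_c, n_expr_c - n_sig_c]], dtype=float
    )
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError(f"degenerate 2x2 table with an empty margin: {table.tolist()}")
    chi2, p, _, _ = scipy.stats.chi2_contingency(table, correction=False)
    return EnrichmentResult(
        focal=focal,
        comparison=comparison,
        n_sig_focal=n_sig_f,
        n_expressed_focal=n_expr_f,
        n_sig_comparison=n_sig_c,
        n_expressed_comparison=n_expr_c,
        chi2=float(chi2),
        p_value=float(p),
    )


def classify_deg_category(
    gene_id: str,
    allele: str,
    directions: dict[str, int],
    cell_class_map: dict[str, str] | None = None,
) -> CategoryAssignment:
    """Cell-type category of one significant (gene, allele) DEG.

    ``directions`` maps each cell type where the feature is significant to
    its fold-change sign (+1 / -1).  Rules are evaluated in order:
    neuronal (significant in >= 2 neuronal cell types and <= 1 glial),
    glial (>= 2 glial, <= 1 neuronal), multiple (>= 2 cell types; with
    conflicting directions the gene is excluded as discordant), else
    cell-type specific.
    """
    if cell_class_map is None:
        cell_class_map = DEFAULT_CELL_CLASS_MAP
    if not directions:
        raise ValueError(f"no significant cell types for ({gene_id}, {allele})")
    for ct in directions:
        if ct not in cell_class_map:
            raise KeyError(f"cell type {ct!r} missing from cell_class_map")

    n_neuronal = sum(cell_class_map[ct] == "neuronal" for ct in directions)
    n_glial = sum(cell_class_map[ct] == "glial" for ct in directions)
    if n_neuronal >= 2 and n_glial <= 1:
        category = "neuronal"
    elif n_glial >= 2 and n_neuronal <= 1:
        category = "glial"
    elif len(directions) >= 2:
        signs = set(np.sign(v) for v in directions.values())
        category = "excluded_discordant" if len(signs) > 1 else "multiple"
    else:
        category = "cell_type_specific"
    return CategoryAssignment(
        gene_id=gene_id, allele=allele, category=category, supporting=dict(directions)
    )


def deg_category_table(
    per_celltype_records: pd.DataFrame,
    cell_class_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Categories for every feature significant in at least one cell type.

    ``per_celltype_records`` concatenates per-cell-type DE records (the
    combined ``"all"`` analysis is ignored here).
    """
    sub = per_celltype_records[
        (per_celltype_records["cell_type"] != "all") & per_celltype_records["significant"]
    ]
    rows = []
    for (gene_id, allele), grp in sub.groupby(["gene_id", "allele"], sort=True):
        directions = {
            r.cell_type: (1 if r.log2fc > 0 else -1) for r in grp.itertuples()
        }
        assignment = classify_deg_category(gene_id, allele, directions, cell_class_map)
        rows.append(
            {
                "gene_id": gene_id,
                "allele": allele,
                "category": assignment.category,
                "n_cell_types": len(directions),
                "cell_types": ",".join(sorted(directions)),
            }
        )
    return pd.DataFrame(
        rows, columns=["gene_id", "allele", "category", "n_cell_types", "cell_types"]
    )
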