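"""Synthetic allele-resolved single-nucleus counts with planted XCI structure.

The generator emulates the statistical structure of an F1-hybrid
(M. musculus x M. castaneus) nonrandom-XCI hippocampal snRNA-seq
experiment.  Per cell and gene:

1. total reads ~ negative binomial around a per-(cell type, gene) rate
   scaled by a log-normal per-cell library factor;
2. allele-assignable reads ~ binomial(total, informative_read_fraction)
   (reads overlapping a strain-distinguishing SNP; the strains differ
   roughly every 264 bp, so a minority of reads are informative);
3. read origin ~ binomial with alternate-strain probability 0.5 on
   autosomes or the gene's true escape probability on the X (the
   alternate strain always carries the inactive X in this model);
4. mapping bias flips each alternate-strain read to the reference strain
   independently with probability ``mapping_bias`` (bias is one-directional,
   toward the better-assembled reference genome).

Only allele-assigned reads populate the two output matrices.  The closed
form for the observed alternate-strain fraction under flip bias b is
p' = p(1-b)/[p(1-b) + (1-p) + p*b], which simplifies to p(1-b) because the
denominator is identically 1; it is the oracle for recovery tests.

Planted aging effects change the old-age parameters only: escape gains and
losses for transition-recovery tests, and one-allele multiplicative fold
changes for differential-expression recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
import yaml

from .dataset import AlleleCountDataset

EFFECT_KINDS = ("new_escape", "lost_escape", "increased_escape", "xa_log2fc", "xi_log2fc")

#: Default hippocampal cell types: three neuronal, three glial.
DEFAULT_CELL_TYPES = ("CA1", "DG", "GABA", "Astro", "Oligo", "MG")


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class AgingEffect:
    """One planted old-age effect on a single gene.

    ``magnitude`` is an escape probability for ``new_escape`` (old-age value)
    and ``increased_escape`` (additive increment), ignored for
    ``lost_escape`` (old escape is set to 0), and a log2 fold change for
    ``xa_log2fc`` / ``xi_log2fc``.  ``cell_types`` of None means all.
    """

    gene: str
    kind: str
    magnitude: float = 0.0
    cell_types: list[str] | None = None


@dataclass
class SimulationConfig:
    n_cell_types: int = 6
    cells_per_type_per_sample: int = 170
    n_samples_per_age: int = 4
    n_autosomal_genes: int = 1800
    n_x_genes: int = 200
    baseline_escape_fraction: float = 0.05
    escape_level_range: tuple[float, float] = (0.10, 0.40)
    mapping_bias: float = 0.12
    informative_read_fraction: float = 0.60
    mean_depth_per_cell: float = 5000.0
    dispersion: float = 0.2
    library_sigma: float = 0.25
    celltype_sigma: float = 0.30
    gene_rate_sigma: float = 1.2
    aging_effects: list[AgingEffect] = field(default_factory=list)
    seed: int = 0
    cell_type_names: tuple[str, ...] | None = None

    def cell_types(self) -> tuple[str, ...]:
        if self.cell_type_names is not None:
            return tuple(self.cell_type_names)
        if self.n_cell_types <= len(DEFAULT_CELL_TYPES):
            return DEFAULT_CELL_TYPES[: self.n_cell_types]
        extra = tuple(
            f"type{i}" for i in range(len(DEFAULT_CELL_TYPES), self.n_cell_types)
        )
        return DEFAULT_CELL_TYPES + extra

    def validate(self) -> list[str]:
        report = []
        for name in (
            "n_cell_types",
            "cells_per_type_per_sample",
            "n_samples_per_age",
            "n_autosomal_genes",
            "n_x_genes",
        ):
            if getattr(self, name) <= 0:
                report.append(f"{name} must be positive")
        for name in (
            "baseline_escape_fraction",
            "mapping_bias",
            "informative_read_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                report.append(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth_per_cell <= 0:
            report.append("mean_depth_per_cell must be positive")
        if self.dispersion < 0:
            report.append("dispersion must be non-negative")
        lo, hi = self.escape_level_range
        if not (0 <= lo <= hi <= 1):
            report.append(f"escape_level_range must be ordered within [0, 1], got {self.escape_level_range}")
        for eff in self.aging_effects:
            if eff.kind not in EFFECT_KINDS:
                report.append(f"unknown effect kind {eff.kind!r}")
            if not np.isfinite(eff.magnitude):
                report.append(f"non-finite magnitude for effect on {eff.gene}")
        return report

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        data["escape_level_range"] = list(self.escape_level_range)
        if self.cell_type_names is not None:
            data["cell_type_names"] = list(self.cell_type_names)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        data = yaml.safe_load(Path(path).read_text())
        effects = [AgingEffect(**e) for e in data.pop("aging_effects", [])]
        if "escape_level_range" in data:
            data["escape_level_range"] = tuple(data["escape_level_range"])
        if data.get("cell_type_names") is not None:
            data["cell_type_names"] = tuple(data["cell_type_names"])
        return cls(aging_effects=effects, **data)


@dataclass
class GroundTruth:
    """Planted parameters behind a simulated dataset.

    Arrays are cell types x genes.  ``escape_young``/``escape_old`` hold the
    true alternate-strain (inactive-X) origin probability per gene: 0.5 on
    autosomes, the escape probability on the X.  ``mult_xa_old`` and
    ``mult_xi_old`` are old-age multiplicative fold changes applied to the
    per-allele expression rates.
    """

    genes: pd.DataFrame  # gene_id, chromosome, baseline_escapee
    cell_types: tuple[str, ...]
    rates: np.ndarray  # baseline total expression rate (reads/cell)
    escape_young: np.ndarray
    escape_old: np.ndarray
    mult_xa_old: np.ndarray
    mult_xi_old: np.ndarray
    effects: pd.DataFrame  # gene_id, kind, magnitude, cell_types

    def gene_index(self, gene_id: str) -> int:
        idx = np.flatnonzero(self.genes["gene_id"].to_numpy() == gene_id)
        if idx.size == 0:
            raise ConfigError(f"unknown gene in aging effect: {gene_id!r}")
        return int(idx[0])

    def to_frames(self) -> dict[str, pd.DataFrame]:
        """Long-format truth tables, suitable for TSV export."""
        gene_ids = self.genes["gene_id"].to_numpy()
        rows = []
        for ct_i, ct in enumerate(self.cell_types):
            for age, esc in (("young", self.escape_young), ("old", self.escape_old)):
                rows.append(
                    pd.DataFrame(
                        {
                            "gene_id": gene_ids,
                            "cell_type": ct,
                            "age_group": age,
                            "rate": self.rates[ct_i],
                            "escape_prob": esc[ct_i],
                            "mult_xa": self.mult_xa_old[ct_i] if age == "old" else 1.0,
                            "mult_xi": self.mult_xi_old[ct_i] if age == "old" else 1.0,
                        }
                    )
                )
        return {
            "genes": self.genes,
            "parameters": pd.concat(rows, ignore_index=True),
            "effects": self.effects,
        }


def write_truth(truth: GroundTruth, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, frame in truth.to_frames().items():
        frame.to_csv(out / f"truth_{name}.tsv", sep="\t", index=False, float_format="%.10g")


def _gene_table(config: SimulationConfig) -> pd.DataFrame:
    auto_ids = [f"auto_{i + 1:04d}" for i in range(config.n_autosomal_genes)]
    auto_chroms = [str(1 + i % 19) for i in range(config.n_autosomal_genes)]
    x_ids = [f"x_{i + 1:04d}" for i in range(config.n_x_genes)]
    return pd.DataFrame(
        {
            "gene_id": auto_ids + x_ids,
            "chromosome": auto_chroms + ["X"] * config.n_x_genes,
        }
    )


def build_truth(config: SimulationConfig) -> GroundTruth:
    """Assign chromosomes, expression rates, baseline escapees, and effects.

    Baseline escapees number ``round(baseline_escape_fraction * n_x_genes)``
    with escape probabilities uniform on ``escape_level_range``.  Genes
    targeted by ``lost_escape``/``increased_escape``/``xi_log2fc`` effects
    are forced into the baseline escapee set (the effects presuppose young
    escape); ``new_escape`` targets are forced out of it.  Genes named in
    any effect get their baseline rate floored at the 75th percentile of
    simulated rates, so recovery tests probe the statistics rather than the
    detection limit.
    """
    problems = config.validate()
    if problems:
        raise ConfigError("; ".join(problems))

    rng = np.random.default_rng(config.seed)
    genes = _gene_table(config)
    gene_ids = genes["gene_id"].to_numpy()
    n_genes = len(genes)
    n_ct = config.n_cell_types
    is_x = (genes["chromosome"] == "X").to_numpy()
    x_indices = np.flatnonzero(is_x)

    id_to_idx = {g: i for i, g in enumerate(gene_ids)}
    for eff in config.aging_effects:
        if eff.gene not in id_to_idx:
            raise ConfigError(f"unknown gene in aging effect: {eff.gene!r}")
        if eff.kind in ("new_escape", "lost_escape", "increased_escape", "xi_log2fc") and not is_x[
            id_to_idx[eff.gene]
        ]:
            raise ConfigError(f"effect {eff.kind} requires an X-linked gene, got {eff.gene!r}")

    base = rng.lognormal(0.0, config.gene_rate_sigma, n_genes)
    effect_idx = np.array(
        sorted({id_to_idx[e.gene] for e in config.aging_effects}), dtype=int
    )
    if effect_idx.size:
        floor = np.quantile(base, 0.75)
        base[effect_idx] = np.maximum(base[effect_idx], floor)
    ct_factor = rng.lognormal(0.0, config.celltype_sigma, (n_ct, n_genes))
    rates = base[None, :] * ct_factor
    rates *= config.mean_depth_per_cell / rates.sum(axis=1, keepdims=True)

    forced_escapees = {
        id_to_idx[e.gene]
        for e in config.aging_effects
        if e.kind in ("lost_escape", "increased_escape", "xi_log2fc")
    }
    forced_silent = {
        id_to_idx[e.gene] for e in config.aging_effects if e.kind == "new_escape"
    }
    overlap = forced_escapees & forced_silent
    if overlap:
        raise ConfigError(
            f"genes planted both escapee and new_escape: {sorted(gene_ids[i] for i in overlap)}"
        )

    n_escapees = int(round(config.baseline_escape_fraction * config.n_x_genes))
    pool = [i for i in x_indices if i not in forced_escapees and i not in forced_silent]
    n_random = max(0, n_escapees - len(forced_escapees))
    chosen = rng.choice(len(pool), size=min(n_random, len(pool)), replace=False)
    escapee_idx = sorted(forced_escapees | {pool[i] for i in chosen})

    escape_levels = np.zeros(n_genes)
    lo, hi = config.escape_level_range
    escape_levels[escapee_idx] = rng.uniform(lo, hi, len(escapee_idx))

    escape_young = np.where(is_x, escape_levels, 0.5)[None, :].repeat(n_ct, axis=0)
    escape_old = escape_young.copy()
    mult_xa_old = np.ones((n_ct, n_genes))
    mult_xi_old = np.ones((n_ct, n_genes))

    cell_types = config.cell_types()
    ct_index = {ct: i for i, ct in enumerate(cell_types)}
    for eff in config.aging_effects:
        g = id_to_idx[eff.gene]
        if eff.cell_types is None:
            cts = list(range(n_ct))
        else:
            unknown = [c for c in eff.cell_types if c not in ct_index]
            if unknown:
                raise ConfigError(f"unknown cell types in aging effect: {unknown}")
            cts = [ct_index[c] for c in eff.cell_types]
        if eff.kind == "new_escape":
            escape_young[:, g] = 0.0
            escape_old[:, g] = 0.0
            escape_old[cts, g] = eff.magnitude
        elif eff.kind == "lost_escape":
            escape_old[cts, g] = 0.0
        elif eff.kind == "increased_escape":
            escape_old[cts, g] = np.minimum(0.95, escape_young[cts, g] + eff.magnitude)
        elif eff.kind == "xa_log2fc":
            mult_xa_old[cts, g] = 2.0 ** eff.magnitude
        elif eff.kind == "xi_log2fc":
            mult_xi_old[cts, g] = 2.0 ** eff.magnitude

    genes = genes.assign(baseline_escapee=np.isin(np.arange(n_genes), escapee_idx))
    effects = pd.DataFrame(
        {
            "gene_id": [e.gene for e in config.aging_effects],
            "kind": [e.kind for e in config.aging_effects],
            "magnitude": [e.magnitude for e in config.aging_effects],
            "cell_types": [
                "all" if e.cell_types is None else ",".join(e.cell_types)
                for e in config.aging_effects
            ],
        }
    )
    return GroundTruth(
        genes=genes,
        cell_types=cell_types,
        rates=rates,
        escape_young=escape_young,
        escape_old=escape_old,
        mult_xa_old=mult_xa_old,
        mult_xi_old=mult_xi_old,
        effects=effects,
    )


def simulate_dataset(
    truth: GroundTruth, config: SimulationConfig
) -> tuple[AlleleCountDataset, GroundTruth]:
    """Draw an allele-resolved dataset from planted truth; deterministic per seed."""
    rng = np.random.default_rng([config.seed, 1])
    n_genes = len(truth.genes)
    cell_types = truth.cell_types

    xa_blocks: list[np.ndarray] = []
    xi_blocks: list[np.ndarray] = []
    cell_rows: list[pd.DataFrame] = []
    cell_counter = 0

    for age, escape in (("young", truth.escape_young), ("old", truth.escape_old)):
        for s in range(config.n_samples_per_age):
            sample_id = f"{age}_{s + 1}"
            for ct_i, ct in enumerate(cell_types):
                nc = config.cells_per_type_per_sample
                rate = truth.rates[ct_i]
                p_alt = escape[ct_i]
                r_alt = rate * p_alt
                r_ref = rate * (1.0 - p_alt)
                if age == "old":
                    r_ref = r_ref * truth.mult_xa_old[ct_i]
                    r_alt = r_alt * truth.mult_xi_old[ct_i]
                total_rate = r_ref + r_alt
                with np.errstate(invalid="ignore", divide="ignore"):
                    p_origin = np.where(total_rate > 0, r_alt / np.maximum(total_rate, 1e-300), 0.0)

                lib = rng.lognormal(0.0, config.library_sigma, nc)
                mu = lib[:, None] * total_rate[None, :]
                if config.dispersion > 0:
                    lam = rng.gamma(1.0 / config.dispersion, config.dispersion * mu)
                else:
                    lam = mu
                counts = rng.poisson(lam)
                informative = rng.binomial(counts, config.informative_read_fraction)
                alt = rng.binomial(informative, p_origin[None, :])
                flipped = rng.binomial(alt, config.mapping_bias)
                xi = alt - flipped
                xa = informative - xi

                xa_blocks.append(xa)
                xi_blocks.append(xi)
                cell_rows.append(
                    pd.DataFrame(
                        {
                            "barcode": [
                                f"c{cell_counter + j:06d}" for j in range(nc)
                            ],
                            "cell_type": ct,
                            "sample_id": sample_id,
                            "age_group": age,
                        }
                    )
                )
                cell_counter += nc

    counts_xa = sp.csr_matrix(np.vstack(xa_blocks).astype(np.int64))
    counts_xi = sp.csr_matrix(np.vstack(xi_blocks).astype(np.int64))
    cells = pd.concat(cell_rows, ignore_index=True)
    ds = AlleleCountDataset(counts_xa, counts_xi, cells, truth.genes[["gene_id", "chromosome"]].copy())
    return ds, truth


def default_paper_like_config(seed: int = 0) -> SimulationConfig:
    """Study-condition defaults: strain splits and escape scale of the
    F1-hybrid hippocampal experiment, with planted aging effects.

    With flip bias b = 0.12 the expected pooled autosomal reference-strain
    share is 0.5(1 + b) = 0.56 (the observed 56/44 split), and with ~5% of
    X genes escaping at levels 0.10-0.40 the pooled X reference share stays
    well above 0.85.
    """
    effects: list[AgingEffect] = []
    effects += [
        AgingEffect(gene=f"x_{100 + i:04d}", kind="new_escape", magnitude=0.25)
        for i in range(1, 7)
    ]
    effects += [
        AgingEffect(gene=f"x_{110 + i:04d}", kind="lost_escape") for i in range(1, 4)
    ]
    effects += [
        AgingEffect(gene=f"x_{120 + i:04d}", kind="increased_escape", magnitude=0.2)
        for i in range(1, 3)
    ]
    effects += [
        AgingEffect(gene=f"x_{130 + i:04d}", kind="xi_log2fc", magnitude=2.0)
        for i in range(1, 3)
    ]
    effects += [
        AgingEffect(gene=f"auto_{100 + i:04d}", kind="xa_log2fc", magnitude=2.0)
        for i in range(1, 7)
    ]
    effects += [
        AgingEffect(gene=f"auto_{110 + i:04d}", kind="xa_log2fc", magnitude=-2.0)
        for i in range(1, 5)
    ]
    return SimulationConfig(aging_effects=effects, seed=seed)
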