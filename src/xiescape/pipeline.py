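"""End-to-end pipeline: simulate/load -> validate -> pseudobulk -> escape ->
transitions -> differential expression -> enrichment, with a run manifest.

Every stage writes plain TSV; identical config and seed give byte-identical
tables.  Stage failures surface as :class:`PipelineStageError` naming the
stage.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dataset import AlleleCountDataset, read_allele_dataset, validate_dataset, write_dataset
from .simulate import SimulationConfig, build_truth, default_paper_like_config, simulate_dataset, write_truth
from .pseudobulk import aggregate, integer_pseudobulk, normalize_cells
from .escape import (
    DEPTH_PERCENTILE,
    ESCAPE_MIN,
    Z_99,
    autosomal_bias_ratio,
    call_escape_table,
)
from .transitions import (
    DegenerateTestError,
    classify_transitions_table,
    cross_celltype_table,
    summarize_sankey,
    paired_escape_change_test,
    xi_dotplot_stats,
)
from .de import (
    DE_ALPHA,
    DE_LFC,
    DEFAULT_CELL_CLASS_MAP,
    chromosome_enrichment,
    deg_category_table,
    run_de_for_cell_type,
)

logger = logging.getLogger(__name__)

_FLOAT_FORMAT = "%.10g"


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Run configuration; thresholds default to the printed analysis constants."""

    out_dir: str
    bundle: str | None = None  # read an existing dataset bundle ...
    simulate: bool = True  # ... or simulate one
    simulation: SimulationConfig | None = None
    seed: int = 0
    target_sum: float = 1e4
    escape_min: float = ESCAPE_MIN
    z: float = Z_99
    depth_percentile: float = DEPTH_PERCENTILE
    de_alpha: float = DE_ALPHA
    de_lfc: float = DE_LFC
    cell_class_map: dict = field(default_factory=lambda: dict(DEFAULT_CELL_CLASS_MAP))

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if self.simulation is not None:
            data["simulation"]["escape_level_range"] = list(self.simulation.escape_level_range)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        sim = data.pop("simulation", None)
        if sim is not None:
            from .simulate import AgingEffect

            effects = [AgingEffect(**e) for e in sim.pop("aging_effects", [])]
            if "escape_level_range" in sim:
                sim["escape_level_range"] = tuple(sim["escape_level_range"])
            if sim.get("cell_type_names") is not None:
                sim["cell_type_names"] = tuple(sim["cell_type_names"])
            sim = SimulationConfig(aging_effects=effects, **sim)
        return cls(simulation=sim, **data)


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FORMAT)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": __version__,
        "seed": config.seed,
        "config": {
            k: v
            for k, v in asdict(config).items()
            if k not in ("simulation",)
        },
        "stages": {},
        "outputs": {},
    }

    def stage(name):
        class _Stage:
            def __enter__(self):
                self.t0 = time.perf_counter()
                logger.info("[%s] start", name)
                return self

            def __exit__(self, exc_type, exc, tb):
                elapsed = time.perf_counter() - self.t0
                manifest["stages"][name] = {
                    "seconds": round(elapsed, 3),
                    "ok": exc is None,
                }
                if exc is not None:
                    _dump_manifest(manifest, out)
                    raise PipelineStageError(name, exc) from exc
                logger.info("[%s] done in %.2fs", name, elapsed)
                return False

        return _Stage()

    with stage("input"):
        if config.bundle is not None and not config.simulate:
            ds = read_allele_dataset(config.bundle)
        else:
            sim = config.simulation or default_paper_like_config()
            sim.seed = config.seed
            truth = build_truth(sim)
            ds, truth = simulate_dataset(truth, sim)
            write_dataset(ds, out / "bundle")
            write_truth(truth, out / "bundle")
            manifest["outputs"]["bundle"] = str(out / "bundle")
        violations = validate_dataset(ds)
        # Runnability advisories (no X / no autosomal gene) are left to the
        # stage that needs them, so its error names the failing analysis.
        structural = [v for v in violations if not v.startswith("no ")]
        for v in violations:
            if v.startswith("no "):
                logger.warning("dataset advisory: %s", v)
        if structural:
            raise ValueError(f"invalid dataset: {structural[:5]}")

    with stage("pseudobulk"):
        factors = normalize_cells(ds, config.target_sum)
        pb_ct_age = aggregate(ds, factors, "celltype_age")
        pb_age = aggregate(ds, factors, "age")
        pb_ct_sample = integer_pseudobulk(ds, "celltype_sample")
        _write_tsv(pb_ct_age.to_long(), out / "pseudobulk_celltype_age.tsv")
        manifest["outputs"]["pseudobulk"] = str(out / "pseudobulk_celltype_age.tsv")

    with stage("escape"):
        ratio = autosomal_bias_ratio(pb_ct_age)
        calls_ct = call_escape_table(
            pb_ct_age,
            ratio,
            escape_min=config.escape_min,
            z=config.z,
            depth_percentile=config.depth_percentile,
        )
        calls_all = call_escape_table(
            pb_age,
            ratio,
            escape_min=config.escape_min,
            z=config.z,
            depth_percentile=config.depth_percentile,
        )
        calls = pd.concat([calls_all, calls_ct], ignore_index=True)
        _write_tsv(calls, out / "escape_calls.tsv")
        manifest["outputs"]["escape_calls"] = str(out / "escape_calls.tsv")
        manifest["bias_ratio"] = {
            "a_t_cast": ratio.a_t_cast,
            "a_t_mus": ratio.a_t_mus,
            "ratio": ratio.ratio,
        }

    with stage("transitions"):
        records = classify_transitions_table(calls)
        sankey = summarize_sankey(records)
        crosses = cross_celltype_table(records[records["cell_type"] != "all"])
        _write_tsv(records, out / "transitions.tsv")
        sankey_counts = sankey.counts.copy()
        sankey_counts.insert(0, "cell_type", sankey_counts.index)
        sankey_counts["n_detected"] = sankey.n_detected.reindex(sankey.counts.index).to_numpy()
        _write_tsv(sankey_counts.reset_index(drop=True), out / "sankey_counts.tsv")
        _write_tsv(crosses, out / "cross_celltype_patterns.tsv")

        interesting = sorted(
            set(
                records.loc[
                    records["category"].isin(("increased", "lost", "new_escape")),
                    "gene_id",
                ]
            )
        )
        if interesting:
            dotplot = xi_dotplot_stats(ds, factors, interesting)
            _write_tsv(dotplot, out / "dotplot_stats.tsv")
            manifest["outputs"]["dotplot"] = str(out / "dotplot_stats.tsv")

        paired_rows = []
        for category in ("lost", "increased", "new_escape"):
            sub = records[
                (records["category"] == category) & (records["cell_type"] != "all")
            ]
            pairs = sub[["young_p_escadj", "old_p_escadj"]].dropna().to_numpy()
            try:
                t, p, n = paired_escape_change_test(pairs)
            except DegenerateTestError:
                t, p, n = np.nan, np.nan, len(pairs)
            paired_rows.append({"category": category, "t_stat": t, "p_value": p, "n": n})
        _write_tsv(pd.DataFrame(paired_rows), out / "paired_escape_tests.tsv")
        manifest["outputs"]["transitions"] = str(out / "transitions.tsv")
        manifest["outputs"]["sankey"] = str(out / "sankey_counts.tsv")

    with stage("differential_expression"):
        sample_ages = dict(
            ds.cells.drop_duplicates("sample_id")[["sample_id", "age_group"]].itertuples(
                index=False, name=None
            )
        )
        cell_types = sorted(ds.cells["cell_type"].unique())
        deg_frames = [
            run_de_for_cell_type(
                pb_ct_sample, ct, sample_ages, alpha=config.de_alpha, lfc=config.de_lfc
            )
            for ct in ["all", *cell_types]
        ]
        deg = pd.concat(deg_frames, ignore_index=True)
        deg["neg_log10_p_adjusted"] = -np.log10(np.maximum(deg["p_adjusted"], 1e-300))
        _write_tsv(deg, out / "deg_records.tsv")
        manifest["outputs"]["deg"] = str(out / "deg_records.tsv")

    with stage("enrichment"):
        gene_chrom = dict(ds.genes[["gene_id", "chromosome"]].itertuples(index=False, name=None))
        enrich_rows = []
        for ct in ["all", *cell_types]:
            sub = deg[deg["cell_type"] == ct]
            expressed = list(zip(sub["gene_id"], sub["allele"]))
            sig = [
                (g, a)
                for g, a, s in zip(sub["gene_id"], sub["allele"], sub["significant"])
                if s
            ]
            comparisons = ["autosomes"]
            if ct == "all":
                comparisons += sorted(
                    {c for c in ds.genes["chromosome"].unique() if c != "X"},
                    key=lambda c: int(c) if c.isdigit() else 99,
                )
            for comparison in comparisons:
                try:
                    res = chromosome_enrichment(
                        sig, expressed, gene_chrom, focal="X", comparison=comparison
                    )
                except ValueError:
                    continue
                enrich_rows.append({"cell_type": ct, **asdict(res)})
        enrich_cols = [
            "cell_type",
            "focal",
            "comparison",
            "n_sig_focal",
            "n_expressed_focal",
            "n_sig_comparison",
            "n_expressed_comparison",
            "chi2",
            "p_value",
        ]
        _write_tsv(pd.DataFrame(enrich_rows, columns=enrich_cols), out / "enrichment.tsv")
        manifest["outputs"]["enrichment"] = str(out / "enrichment.tsv")

        categories = deg_category_table(deg, config.cell_class_map)
        _write_tsv(categories, out / "deg_categories.tsv")
        manifest["outputs"]["deg_categories"] = str(out / "deg_categories.tsv")

    with stage("report"):
        report = make_report(out)
        (out / "report.txt").write_text(report)
        manifest["outputs"]["report"] = str(out / "report.txt")

    _dump_manifest(manifest, out)
    return manifest


def _dump_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))


def make_report(out_dir: str | Path) -> str:
    """Human-readable summary assembled from the stage output tables."""
    out = Path(out_dir)
    lines = ["xiescape run summary", "====================", ""]

    calls_path = out / "escape_calls.tsv"
    if calls_path.is_file():
        calls = pd.read_csv(calls_path, sep="\t")
        combined = calls[calls["cell_type"] == "all"]
        detected = (
            combined.groupby("gene_id")[["xi_reads", "xa_reads"]].sum().sum(axis=1) > 0
        ).sum()
        lines.append(f"detected X genes (combined cells): {int(detected)}")
        for age in ("young", "old"):
            n_esc = int(
                (combined.loc[combined["age_group"] == age, "status"] == "escapee").sum()
            )
            lines.append(f"escapees, combined cells, {age}: {n_esc}")
        lines.append("")

    sankey_path = out / "sankey_counts.tsv"
    if sankey_path.is_file():
        sankey = pd.read_csv(sankey_path, sep="\t")
        lines.append("escape transition counts per cell type:")
        lines.append(sankey.to_string(index=False))
        lines.append("")
    else:
        lines.append("zero classified genes (no transition table)")
        lines.append("")

    deg_path = out / "deg_records.tsv"
    if deg_path.is_file():
        deg = pd.read_csv(deg_path, sep="\t")
        genes_path = out / "bundle" / "genes.tsv"
        chrom = None
        if genes_path.is_file():
            genes = pd.read_csv(genes_path, sep="\t", dtype=str)
            chrom = dict(zip(genes["gene_id"], genes["chromosome"]))
        for ct, sub in deg.groupby("cell_type"):
            n_sig = int(sub["significant"].sum())
            line = f"DEGs in {ct}: {n_sig} significant of {len(sub)} tested features"
            if chrom is not None and n_sig:
                n_sig_x = int(
                    sum(
                        s and chrom.get(g) == "X"
                        for g, s in zip(sub["gene_id"], sub["significant"])
                    )
                )
                line += f" ({n_sig_x} X-linked)"
            lines.append(line)
        lines.append("")

    enr_path = out / "enrichment.tsv"
    if enr_path.is_file():
        enr = pd.read_csv(enr_path, sep="\t")
        combined = enr[(enr["cell_type"] == "all") & (enr["comparison"] == "autosomes")]
        if len(combined):
            row = combined.iloc[0]
            lines.append(
                "X vs autosome enrichment (combined cells): "
                f"chi2={row['chi2']:.3f}, p={row['p_value']:.4g} "
                f"({row['n_sig_focal']}/{row['n_expressed_focal']} X vs "
                f"{row['n_sig_comparison']}/{row['n_expressed_comparison']} autosomal)"
            )
    return "\n".join(lines) + "\n"
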