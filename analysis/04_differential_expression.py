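#!/usr/bin/env python
"""Pseudobulk allele-level differential expression and X enrichment.

Fits old-versus-young negative-binomial Wald tests per (gene, allele)
feature for each cell type and for all cells combined, then tests whether
significant DEGs are overrepresented on the X relative to autosomes
(including size-matched single-autosome comparisons), and classifies
X-linked DEGs into neuronal/glial/multiple/cell-type-specific categories.
"""

from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from xiescape import (
    chromosome_enrichment,
    deg_category_table,
    read_allele_dataset,
    run_de_for_cell_type,
)
from xiescape.pseudobulk import integer_pseudobulk

BUNDLE = Path("results/sim")
RESULTS = Path("results")


def main() -> None:
    ds = read_allele_dataset(BUNDLE)
    pb = integer_pseudobulk(ds, "celltype_sample")
    sample_ages = dict(
        ds.cells.drop_duplicates("sample_id")[["sample_id", "age_group"]].itertuples(
            index=False, name=None
        )
    )
    cell_types = sorted(ds.cells["cell_type"].unique())
    frames = [run_de_for_cell_type(pb, ct, sample_ages) for ct in ["all", *cell_types]]
    deg = pd.concat(frames, ignore_index=True)
    deg["neg_log10_p_adjusted"] = -np.log10(np.maximum(deg["p_adjusted"], 1e-300))
    deg.to_csv(RESULTS / "deg_records.tsv", sep="\t", index=False, float_format="%.10g")

    gene_chrom = dict(ds.genes[["gene_id", "chromosome"]].itertuples(index=False, name=None))
    rows = []
    for ct in ["all", *cell_types]:
        sub = deg[deg["cell_type"] == ct]
        expressed = list(zip(sub["gene_id"], sub["allele"]))
        sig = [f for f, s in zip(expressed, sub["significant"]) if s]
        print(f"{ct}: {len(sig)} significant of {len(expressed)} tested features")
        comparisons = ["autosomes"]
        if ct == "all":
            comparisons += sorted(
                {c for c in ds.genes["chromosome"].unique() if c != "X"},
                key=lambda c: int(c) if c.isdigit() else 99,
            )
        for comparison in comparisons:
            try:
                res = chromosome_enrichment(sig, expressed, gene_chrom, comparison=comparison)
            except ValueError:
                continue
            rows.append({"cell_type": ct, **asdict(res)})
            if comparison == "autosomes":
                print(
                    f"  X vs autosomes: {res.n_sig_focal}/{res.n_expressed_focal} vs "
                    f"{res.n_sig_comparison}/{res.n_expressed_comparison}, "
                    f"chi2={res.chi2:.3f}, p={res.p_value:.3g}"
                )
    pd.DataFrame(rows).to_csv(
        RESULTS / "enrichment.tsv", sep="\t", index=False, float_format="%.10g"
    )

    categories = deg_category_table(deg)
    categories.to_csv(RESULTS / "deg_categories.tsv", sep="\t", index=False)
    if len(categories):
        print("\nDEG categories:", categories["category"].value_counts().to_dict())


if __name__ == "__main__":
    main()
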