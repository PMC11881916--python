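#!/usr/bin/env python
"""Aging transitions of escape status and Xi-only expression summaries.

Classifies every (X gene, cell type) young->old pair, tabulates Sankey
category counts, flags genes with consistent or mixed patterns across cell
types, computes dot-plot statistics for transition genes, and runs the
paired escape-change tests per category.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from xiescape import (
    classify_transitions_table,
    normalize_cells,
    paired_escape_change_test,
    read_allele_dataset,
    summarize_sankey,
    xi_dotplot_stats,
)
from xiescape.transitions import DegenerateTestError, cross_celltype_table

BUNDLE = Path("results/sim")
CALLS = Path("results/escape_calls.tsv")
RESULTS = Path("results")


def main() -> None:
    calls = pd.read_csv(CALLS, sep="\t")
    records = classify_transitions_table(calls)
    records.to_csv(RESULTS / "transitions.tsv", sep="\t", index=False, float_format="%.10g")

    sankey = summarize_sankey(records)
    counts = sankey.counts.reset_index()
    counts["n_detected"] = sankey.n_detected.reindex(sankey.counts.index).to_numpy()
    counts.to_csv(RESULTS / "sankey_counts.tsv", sep="\t", index=False)
    print("transition counts per cell type:")
    print(counts.to_string(index=False))

    crosses = cross_celltype_table(records[records["cell_type"] != "all"])
    crosses.to_csv(RESULTS / "cross_celltype_patterns.tsv", sep="\t", index=False)
    n_mixed = int((crosses["pattern"] == "mixed").sum())
    print(f"\ngenes informative across cell types: {len(crosses)} ({n_mixed} mixed)")

    ds = read_allele_dataset(BUNDLE)
    factors = normalize_cells(ds)
    interesting = sorted(
        set(records.loc[records["category"].isin(("increased", "lost", "new_escape")), "gene_id"])
    )
    if interesting:
        stats = xi_dotplot_stats(ds, factors, interesting)
        stats.to_csv(RESULTS / "dotplot_stats.tsv", sep="\t", index=False, float_format="%.10g")
        print(f"dot-plot stats for {len(interesting)} transition genes -> results/dotplot_stats.tsv")

    rows = []
    for category in ("lost", "increased", "new_escape"):
        sub = records[(records["category"] == category) & (records["cell_type"] != "all")]
        pairs = sub[["young_p_escadj", "old_p_escadj"]].dropna().to_numpy()
        try:
            t, p, n = paired_escape_change_test(pairs)
            print(f"paired test, {category}: t={t:.3f}, p={p:.3g}, n={n}")
        except DegenerateTestError as exc:
            t, p, n = np.nan, np.nan, len(pairs)
            print(f"paired test, {category}: degenerate ({exc})")
        rows.append({"category": category, "t_stat": t, "p_value": p, "n": n})
    pd.DataFrame(rows).to_csv(
        RESULTS / "paired_escape_tests.tsv", sep="\t", index=False, float_format="%.10g"
    )


if __name__ == "__main__":
    main()
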