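#!/usr/bin/env python
"""Generate the study-scale synthetic dataset with planted aging effects.

Writes the allele-resolved bundle plus ground-truth tables under
``results/sim/`` and prints the pooled strain splits, which should sit near
the 56/44 autosomal and >85/15 X-linked reference/alternate splits of the
nonrandom-XCI hybrid model.
"""

from pathlib import Path

from xiescape import build_truth, default_paper_like_config, simulate_dataset, write_dataset
from xiescape.simulate import write_truth

OUT = Path("results/sim")
SEED = 0


def main() -> None:
    config = default_paper_like_config(seed=SEED)
    truth = build_truth(config)
    ds, truth = simulate_dataset(truth, config)
    write_dataset(ds, OUT)
    write_truth(truth, OUT)
    config.to_yaml(OUT / "sim_config.yaml")

    x = ds.x_mask()
    auto_xa = ds.counts_xa[:, ~x].sum()
    auto_xi = ds.counts_xi[:, ~x].sum()
    x_xa = ds.counts_xa[:, x].sum()
    x_xi = ds.counts_xi[:, x].sum()
    print(f"wrote {ds.n_cells} cells x {ds.n_genes} genes to {OUT}")
    print(
        f"autosomal split: {100 * auto_xa / (auto_xa + auto_xi):.1f}% reference / "
        f"{100 * auto_xi / (auto_xa + auto_xi):.1f}% alternate"
    )
    print(
        f"X-linked split:  {100 * x_xa / (x_xa + x_xi):.1f}% reference / "
        f"{100 * x_xi / (x_xa + x_xi):.1f}% alternate"
    )
    n_esc = int(truth.genes["baseline_escapee"].sum())
    print(f"planted baseline escapees: {n_esc} of {int(x.sum())} X genes")
    print(f"planted aging effects: {len(truth.effects)}")


if __name__ == "__main__":
    main()
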