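"""Differential-expression engine, significance rules, enrichment, categories."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from xiescape import (
    call_significant,
    chromosome_enrichment,
    classify_deg_category,
    filter_de_genes,
    fit_pseudobulk_de,
)


def nb_counts(rng, mu, alpha, size):
    """Negative binomial draws with mean mu and dispersion alpha."""
    if alpha <= 0:
        return rng.poisson(mu, size=size)
    return rng.poisson(rng.gamma(1.0 / alpha, alpha * mu, size=size))


class TestFilter:
    @pytest.mark.parametrize(
        "counts, retained",
        [
            ([3, 3, 3], False),  # total 9 < 10
            ([12, 0], True),  # total 12, max 12
            ([6, 6], False),  # total 12 but no single sample reaches 10
            ([10, 0, 0], True),
            ([9, 1], False),
        ],
    )
    def test_rule_examples(self, counts, retained):
        mask = filter_de_genes(np.array([counts]))
        assert mask.tolist() == [retained]

    def test_matches_brute_force_on_boundary_grid(self):
        grid = [0, 1, 9, 10, 11]
        rows = np.array(list(itertools.product(grid, repeat=3)))
        mask = filter_de_genes(rows)
        oracle = np.array([(r.sum() >= 10) and (r.max() >= 10) for r in rows])
        assert np.array_equal(mask, oracle)

    def test_every_sample_mode(self):
        rows = np.array([[10, 9], [10, 10]])
        mask = filter_de_genes(rows, require_every_sample=True)
        assert mask.tolist() == [False, True]


class TestCallSignificant:
    def test_matches_rule_enumeration_on_boundary_grid(self):
        p_grid = [0.049, 0.05, 0.051]
        lfc_grid = [-0.11, -0.1, 0.0, 0.1, 0.11]
        rows = pd.DataFrame(
            [(p, l) for p, l in itertools.product(p_grid, lfc_grid)],
            columns=["p_adjusted", "log2fc"],
        )
        got = call_significant(rows)
        oracle = [
            (p < 0.05) and (l > 0.1 or l < -0.1)
            for p, l in zip(rows["p_adjusted"], rows["log2fc"])
        ]
        assert got.tolist() == oracle

    @pytest.mark.parametrize(
        "p_adj, lfc, expected",
        [(0.049, 0.11, True), (0.05, 0.5, False), (0.01, 0.1, False)],
    )
    def test_strict_thresholds(self, p_adj, lfc, expected):
        frame = pd.DataFrame({"p_adjusted": [p_adj], "log2fc": [lfc]})
        assert call_significant(frame).tolist() == [expected]


class TestFitPseudobulkDE:
    def features(self, n):
        return [(f"g{i}", "xa_strain") for i in range(n)]

    def test_identical_ages_give_zero_log2fc(self):
        rng = np.random.default_rng(0)
        young = nb_counts(rng, 200.0, 0.05, size=(30, 3))
        counts = np.hstack([young, young])  # old samples copy the young ones
        ages = ["young"] * 3 + ["old"] * 3
        records = fit_pseudobulk_de(counts, ages, self.features(30))
        assert np.allclose(records["log2fc"], 0.0, atol=1e-8)

    def test_null_type_one_error_rate(self):
        # no planted effects: raw p < 0.05 should occur at roughly the
        # nominal rate (Wald tests at n=8 run slightly liberal)
        rng = np.random.default_rng(1)
        counts = nb_counts(rng, 300.0, 0.05, size=(300, 8))
        ages = ["young"] * 4 + ["old"] * 4
        records = fit_pseudobulk_de(counts, ages, self.features(300))
        rate = (records["p_value"] < 0.05).mean()
        assert 0.005 <= rate <= 0.12

    def test_planted_fourfold_effect_recovered(self):
        rng = np.random.default_rng(2)
        base = nb_counts(rng, 500.0, 0.02, size=(50, 8)).astype(float)
        ages = ["young"] * 4 + ["old"] * 4
        planted = [3, 17, 41]
        base[planted, 4:] *= 4.0
        records = fit_pseudobulk_de(base, ages, self.features(50))
        hits = records.iloc[planted]
        assert hits["significant"].all()
        assert np.allclose(hits["log2fc"], 2.0, atol=0.5)

    def test_bh_adjustment_is_monotone(self):
        rng = np.random.default_rng(3)
        counts = nb_counts(rng, 100.0, 0.1, size=(80, 8))
        ages = ["young"] * 4 + ["old"] * 4
        records = fit_pseudobulk_de(counts, ages, self.features(80))
        order_p = np.argsort(records["p_value"].to_numpy(), kind="stable")
        adj_sorted = records["p_adjusted"].to_numpy()[order_p]
        assert (np.diff(adj_sorted) >= -1e-12).all()

    def test_degenerate_design_rejected(self):
        counts = np.ones((5, 4))
        with pytest.raises(ValueError, match="age group"):
            fit_pseudobulk_de(counts, ["young"] * 4, self.features(5))
        with pytest.raises(ValueError, match="2 samples"):
            fit_pseudobulk_de(counts, ["young", "young", "young", "old"], self.features(5))

    def test_cross_check_against_pydeseq2(self):
        # independent oracle: the published NB-Wald implementation should
        # agree on fold-change direction and strong-effect significance
        pydeseq2 = pytest.importorskip("pydeseq2")
        from pydeseq2.dds import DeseqDataSet
        from pydeseq2.ds import DeseqStats

        rng = np.random.default_rng(4)
        n_feat = 40
        counts = nb_counts(rng, 400.0, 0.05, size=(n_feat, 8)).astype(float)
        planted = {1: 4.0, 10: 0.25, 30: 4.0}
        for idx, fold in planted.items():
            counts[idx, 4:] *= fold
        ages = ["young"] * 4 + ["old"] * 4
        ours = fit_pseudobulk_de(counts, ages, self.features(n_feat))

        metadata = pd.DataFrame({"age": ages}, index=[f"s{i}" for i in range(8)])
        dds = DeseqDataSet(
            counts=pd.DataFrame(
                counts.T.astype(int), index=metadata.index, columns=[f"g{i}" for i in range(n_feat)]
            ),
            metadata=metadata,
            design="~age",
            quiet=True,
        )
        dds.deseq2()
        stats = DeseqStats(dds, contrast=["age", "old", "young"], quiet=True)
        stats.summary()
        theirs = stats.results_df

        corr = scipy.stats.pearsonr(ours["log2fc"], theirs["log2FoldChange"]).statistic
        assert corr > 0.9
        for idx, fold in planted.items():
            ref = theirs.iloc[idx]
            mine = ours.iloc[idx]
            assert np.sign(mine["log2fc"]) == np.sign(ref["log2FoldChange"])
            assert mine["p_adjusted"] < 0.05 and ref["padj"] < 0.05


class TestEnrichment:
    @staticmethod
    def hand_chi2(table):
        """Pearson chi-square on a 2x2 table, no continuity correction."""
        table = np.asarray(table, dtype=float)
        total = table.sum()
        expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / total
        return ((table - expected) ** 2 / expected).sum()

    @staticmethod
    def run(n_sig_x, n_expr_x, n_sig_a, n_expr_a, comparison="autosomes"):
        chroms = {}
        expressed = []
        sig = []
        for i in range(n_expr_x):
            g = f"x{i}"
            chroms[g] = "X"
            expressed.append(g)
            if i < n_sig_x:
                sig.append(g)
        for i in range(n_expr_a):
            g = f"a{i}"
            chroms[g] = "7"
            expressed.append(g)
            if i < n_sig_a:
                sig.append(g)
        return chromosome_enrichment(sig, expressed, chroms, comparison=comparison)

    def test_equal_proportions_give_zero(self):
        res = self.run(10, 100, 100, 1000)
        assert res.chi2 == pytest.approx(0.0, abs=1e-12)

    def test_worked_example(self):
        res = self.run(20, 100, 100, 1000)
        assert res.chi2 == pytest.approx(9.3537, abs=1e-3)
        assert res.p_value == pytest.approx(
            scipy.stats.chi2.sf(res.chi2, df=1), abs=1e-12
        )

    def test_matches_hand_oracle_on_random_tables(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            n_expr_x = rng.integers(2, 50)
            n_expr_a = rng.integers(2, 500)
            n_sig_x = rng.integers(1, n_expr_x)
            n_sig_a = rng.integers(1, n_expr_a)
            res = self.run(n_sig_x, n_expr_x, n_sig_a, n_expr_a)
            table = [
                [n_sig_x, n_expr_x - n_sig_x],
                [n_sig_a, n_expr_a - n_sig_a],
            ]
            assert res.chi2 == pytest.approx(self.hand_chi2(table), abs=1e-9)

    def test_swapping_sides_is_symmetric(self):
        res1 = self.run(20, 100, 100, 1000)
        table = [[100, 900], [20, 80]]
        assert self.hand_chi2(table) == pytest.approx(res1.chi2, abs=1e-9)

    def test_single_autosome_comparison(self):
        chroms = {"x0": "X", "a0": "7", "a1": "7", "b0": "8"}
        expressed = list(chroms)
        res = chromosome_enrichment(["x0"], expressed, chroms, comparison="7")
        assert res.n_expressed_comparison == 2

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            self.run(0, 5, 0, 50)


class TestCategories:
    MAP = {
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

    def test_two_neuronal_one_direction(self):
        res = classify_deg_category("g", "xa_strain", {"CA1": 1, "DG": 1}, self.MAP)
        assert res.category == "neuronal"

    def test_two_glial_plus_one_neuronal(self):
        res = classify_deg_category(
            "g", "xa_strain", {"Astro": 1, "Oligo": 1, "CA1": 1}, self.MAP
        )
        assert res.category == "glial"

    def test_discordant_multiple_excluded(self):
        res = classify_deg_category("g", "xa_strain", {"CA1": 1, "Astro": -1}, self.MAP)
        assert res.category == "excluded_discordant"

    def test_concordant_multiple(self):
        res = classify_deg_category("g", "xa_strain", {"CA1": 1, "Astro": 1}, self.MAP)
        assert res.category == "multiple"

    def test_single_cell_type(self):
        res = classify_deg_category("g", "xi_strain", {"Oligo": 1}, self.MAP)
        assert res.category == "cell_type_specific"

    def test_unmapped_cell_type_rejected(self):
        with pytest.raises(KeyError, match="cell_class_map"):
            classify_deg_category("g", "xa_strain", {"Endo": 1}, self.MAP)
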