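"""Escape proportion, bias correction, Wald interval, and status rules."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from xiescape import (
    adjust_escape,
    aggregate,
    autosomal_bias_ratio,
    call_escape_status,
    call_escape_table,
    depth_thresholds,
    escape_interval,
    escape_proportion,
    normalize_cells,
)
from xiescape.escape import NotDetectedError
from xiescape.pseudobulk import PseudobulkTable

import pandas as pd

from conftest import make_dataset


def make_pb(xa, xi, chromosomes, scheme="celltype_age", groups=None):
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xi = np.atleast_2d(np.asarray(xi, dtype=float))
    n_groups, n_genes = xa.shape
    if groups is None:
        groups = pd.DataFrame(
            {"cell_type": [f"ct{i}" for i in range(n_groups)], "age_group": "young"}
        )
    return PseudobulkTable(
        scheme=scheme,
        groups=groups,
        gene_ids=np.array([f"g{j}" for j in range(n_genes)]),
        chromosomes=np.asarray(chromosomes),
        xa=xa,
        xi=xi,
    )


class TestEscapeProportion:
    @pytest.mark.parametrize(
        "xi, xa, expected",
        [(0, 100, 0.0), (50, 50, 0.5), (8.3, 91.7, 0.083)],
    )
    def test_values(self, xi, xa, expected):
        assert escape_proportion(xi, xa) == pytest.approx(expected)

    def test_no_reads_is_not_detected(self):
        with pytest.raises(NotDetectedError):
            escape_proportion(0, 0)


class TestBiasRatio:
    def test_balanced_autosomes_give_unit_ratio(self):
        pb = make_pb([[50, 50]], [[50, 50]], ["1", "2"])
        assert autosomal_bias_ratio(pb).ratio == pytest.approx(1.0)

    def test_printed_56_44_split(self):
        pb = make_pb([[56.0]], [[44.0]], ["1"])
        assert autosomal_bias_ratio(pb).ratio == pytest.approx(11 / 14, abs=1e-12)

    def test_scale_invariance(self):
        pb1 = make_pb([[30, 26]], [[20, 24]], ["1", "2"])
        pb2 = make_pb([[60, 52]], [[40, 48]], ["1", "2"])
        assert autosomal_bias_ratio(pb1).ratio == pytest.approx(
            autosomal_bias_ratio(pb2).ratio
        )

    def test_x_genes_excluded(self):
        pb = make_pb([[56.0, 999.0]], [[44.0, 999.0]], ["1", "X"])
        assert autosomal_bias_ratio(pb).ratio == pytest.approx(11 / 14)

    def test_zero_reference_total_errors(self):
        pb = make_pb([[0.0]], [[44.0]], ["1"])
        with pytest.raises(ValueError):
            autosomal_bias_ratio(pb)


class TestAdjustEscape:
    def test_printed_worked_example(self):
        assert adjust_escape(0.5, 11 / 14) == pytest.approx(14 / 25, abs=1e-15)

    def test_identity_at_unit_ratio(self):
        rng = np.random.default_rng(0)
        for p in rng.uniform(0, 1, 1000):
            assert adjust_escape(p, 1.0) == pytest.approx(p, abs=1e-12)

    def test_zero_maps_to_zero(self):
        assert adjust_escape(0.0, 0.7) == 0.0

    @settings(max_examples=200, derandomize=True)
    @given(
        p1=st.floats(0, 1),
        p2=st.floats(0, 1),
        r=st.floats(0.01, 10),
    )
    def test_monotone_in_proportion(self, p1, p2, r):
        lo, hi = sorted([p1, p2])
        assert adjust_escape(lo, r) <= adjust_escape(hi, r) + 1e-12

    @settings(max_examples=200, derandomize=True)
    @given(
        p=st.floats(0.001, 0.999),
        r1=st.floats(0.01, 10),
        r2=st.floats(0.01, 10),
    )
    def test_antitone_in_ratio(self, p, r1, r2):
        lo, hi = sorted([r1, r2])
        assert adjust_escape(p, hi) <= adjust_escape(p, lo) + 1e-12


class TestEscapeInterval:
    def test_worked_examples(self):
        assert escape_interval(0.5, 100) == pytest.approx((0.37125, 0.62875), abs=1e-12)
        lo, hi = escape_interval(0.2, 10_000)
        assert (lo, hi) == pytest.approx((0.1897, 0.2103), abs=1e-12)

    def test_degenerate_proportion_zero_width(self):
        assert escape_interval(0.0, 50) == (0.0, 0.0)
        assert escape_interval(1.0, 50) == (1.0, 1.0)

    def test_width_shrinks_with_depth(self):
        widths = [np.diff(escape_interval(0.3, n))[0] for n in (10, 100, 1000, 1e6)]
        assert all(a > b for a, b in zip(widths, widths[1:]))

    def test_nonpositive_total_errors(self):
        with pytest.raises(ValueError):
            escape_interval(0.2, 0)


class TestDepthThreshold:
    def test_constant_distribution(self):
        pb = make_pb([[7.0, 7.0]], [[7.0, 7.0]], ["X", "X"])
        assert depth_thresholds(pb) == pytest.approx(7.0)

    def test_linear_interpolation_between_order_stats(self):
        pb = make_pb([[0.0]], [[100.0]], ["X"])
        assert depth_thresholds(pb) == pytest.approx(5.0)

    def test_upper_tail_additions_keep_threshold_in_range(self):
        pb1 = make_pb([[1.0, 2.0, 3.0]], [[4.0, 5.0, 6.0]], ["X"] * 3)
        t1 = depth_thresholds(pb1)
        pb2 = make_pb([[1.0, 2.0, 3.0, 999.0]], [[4.0, 5.0, 6.0, 999.0]], ["X"] * 4)
        assert 1.0 <= depth_thresholds(pb2) <= 999.0
        assert depth_thresholds(pb2) >= t1 - 1e-12

    def test_no_x_genes_errors(self):
        pb = make_pb([[1.0]], [[1.0]], ["1"])
        with pytest.raises(ValueError, match="X-linked"):
            depth_thresholds(pb)


class TestStatusRule:
    def test_escapee_when_all_criteria_met(self):
        assert (
            call_escape_status(xi_reads=10, xa_reads=90, p_escadj=0.10, ci_lower=0.01, threshold=5)
            == "escapee"
        )

    def test_zero_ci_lower_bound_is_not_escape(self):
        # "greater than 0" is strict: a clamped lower bound of 0 fails.
        assert (
            call_escape_status(xi_reads=30, xa_reads=70, p_escadj=0.30, ci_lower=0.0, threshold=5)
            == "inactive"
        )

    def test_escape_min_is_strict(self):
        assert (
            call_escape_status(xi_reads=5, xa_reads=95, p_escadj=0.05, ci_lower=0.01, threshold=1)
            == "inactive"
        )

    def test_low_xa_is_not_assessable(self):
        assert (
            call_escape_status(xi_reads=50, xa_reads=1, p_escadj=0.9, ci_lower=0.5, threshold=5)
            == "not_assessable"
        )

    def test_low_xi_blocks_escape_but_stays_inactive(self):
        assert (
            call_escape_status(xi_reads=1, xa_reads=50, p_escadj=0.2, ci_lower=0.1, threshold=5)
            == "inactive"
        )

    def test_threshold_tie_passes(self):
        assert (
            call_escape_status(xi_reads=5, xa_reads=5, p_escadj=0.5, ci_lower=0.2, threshold=5)
            == "escapee"
        )

    def test_no_reads_is_not_detected(self):
        assert call_escape_status(0, 0, np.nan, np.nan, threshold=5) == "not_detected"


class TestCallTable:
    def test_scale_invariance_of_calls(self):
        xa = [[400.0, 300.0, 80.0], [500.0, 200.0, 90.0]]
        xi = [[380.0, 250.0, 20.0], [450.0, 180.0, 1.0]]
        chroms = ["1", "2", "X"]
        pb1 = make_pb(xa, xi, chroms)
        pb2 = make_pb(10 * np.array(xa), 10 * np.array(xi), chroms)
        r1, r2 = autosomal_bias_ratio(pb1), autosomal_bias_ratio(pb2)
        t1 = call_escape_table(pb1, r1)
        t2 = call_escape_table(pb2, r2)
        assert np.allclose(t1["p_esc"], t2["p_esc"])
        assert np.allclose(t1["p_escadj"], t2["p_escadj"])
        assert t1["status"].tolist() == t2["status"].tolist()

    def test_interval_contains_adjusted_estimate(self, small_sim):
        ds, _ = small_sim
        factors = normalize_cells(ds)
        pb = aggregate(ds, factors, "celltype_age")
        calls = call_escape_table(pb, autosomal_bias_ratio(pb))
        detected = calls[calls["xi_reads"] + calls["xa_reads"] > 0]
        assert (detected["ci_lower"] <= detected["p_escadj"] + 1e-12).all()
        assert (detected["ci_upper"] >= detected["p_escadj"] - 1e-12).all()

    def test_bias_correction_recovery_within_tolerance(self):
        # Closed-form oracle: observed p_esc = p(1-b); autosomal ratio
        # (1-b)/(1+b).  The correction must land within 0.02 of truth for
        # planted escape levels at deep counts.
        b = 0.12
        ratio = (1 - b) / (1 + b)
        for p in np.linspace(0.10, 0.40, 13):
            p_obs = p * (1 - b)
            assert abs(adjust_escape(p_obs, ratio) - p) <= 0.02
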