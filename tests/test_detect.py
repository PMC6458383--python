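"""Burst statistic: Poisson tail, BH adjustment, dS estimation, filters,
and the end-to-end scan on small simulated datasets."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import burstscan as bs
from burstscan.detect import (ScanConfig, bh_adjust, ds_consistency_test,
                              estimate_edge_ds, filter_gap_alignments,
                              poisson_tail, scan_bursts)
from burstscan.io import CodonAlignment
from burstscan.simulate import BurstSpec, preset_config, simulate_dataset


class TestPoissonTail:
    @pytest.mark.parametrize("k, lam, expected", [
        (0, 0.3, 1.0),
        (2, 1.0, 1.0 - 2.0 / math.e),
        # partial sum of the first 6 Poisson terms at lambda = 0.5
        (6, 0.5, 1.416494e-5),
    ])
    def test_values(self, k, lam, expected):
        assert poisson_tail(k, lam) == pytest.approx(expected, rel=1e-4)

    def test_matches_term_summation(self):
        # independent oracle: explicit partial sum of Poisson pmf terms
        for k, lam in [(3, 0.7), (8, 2.5), (15, 1.2)]:
            cdf = sum(math.exp(-lam) * lam ** j / math.factorial(j)
                      for j in range(k))
            assert poisson_tail(k, lam) == pytest.approx(1 - cdf, rel=1e-12)

    def test_deep_tail_support(self):
        p = poisson_tail(40, 0.1)
        assert 0 < p < 1e-30

    @given(st.integers(1, 30), st.floats(0.01, 10.0))
    def test_monotone_decreasing_in_k(self, k, lam):
        assert poisson_tail(k + 1, lam) < poisson_tail(k, lam)

    @given(st.integers(1, 30), st.floats(0.01, 10.0))
    def test_monotone_increasing_in_lambda(self, k, lam):
        assert poisson_tail(k, lam * 1.5) > poisson_tail(k, lam)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            poisson_tail(2, 0.0)
        with pytest.raises(ValueError):
            poisson_tail(-1, 1.0)


def _stepup_oracle(pvals):
    """Textbook BH step-up computed by hand-rolled sorting."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * pvals[i] / rank)
        adj[i] = running
    return adj


class TestBHAdjust:
    @pytest.mark.parametrize("pvals, expected", [
        ([0.05], [0.05]),
        ([0.01, 0.02, 0.03], [0.03, 0.03, 0.03]),
        ([0.001, 0.5], [0.002, 0.5]),
    ])
    def test_textbook_examples(self, pvals, expected):
        assert bh_adjust(pvals) == pytest.approx(expected)

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30))
    def test_matches_stepup_oracle_and_dominates_raw(self, pvals):
        adj = bh_adjust(pvals)
        assert adj == pytest.approx(_stepup_oracle(pvals), abs=1e-12)
        assert np.all(adj >= np.asarray(pvals) - 1e-15)
        assert np.all(adj <= 1.0 + 1e-15)

    def test_invalid(self):
        with pytest.raises(ValueError):
            bh_adjust([])
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestEdgeDs:
    def test_closed_form(self):
        assert estimate_edge_ds(150, 30000) == pytest.approx(0.0050167,
                                                             abs=1e-7)

    def test_zero_events_and_linearity(self):
        assert estimate_edge_ds(0, 1000) == 0.0
        p1 = 50 / 30000
        p2 = 100 / 30000
        assert p2 == pytest.approx(2 * p1)  # linear before JC correction

    def test_zero_sites_error(self):
        with pytest.raises(ValueError):
            estimate_edge_ds(10, 0)


class TestDsConsistency:
    def test_zero_events_pass(self):
        p, ok = ds_consistency_test(0, 200, 0.004)
        assert p == 1.0 and ok

    def test_gross_excess_fails(self):
        p, ok = ds_consistency_test(20, 400, 0.00125)  # lambda = 0.5
        assert p < 1e-20 and not ok

    def test_count_at_expectation_passes(self):
        p, ok = ds_consistency_test(2, 500, 0.004)  # lambda = 2, k = 2
        assert p > 0.001 and ok


class TestGapFilter:
    def make(self, frac):
        n = 10
        gap_cols = int(frac * n)
        a = "".join("---" if c < gap_cols else "ATG" for c in range(n))
        b = "ATG" * n
        return CodonAlignment("g", {"A": a, "B": b})

    def test_boundary(self):
        keep, drop = filter_gap_alignments({"exact_half": self.make(0.5),
                                            "sixty": self.make(0.6),
                                            "clean": self.make(0.0)})
        assert sorted(keep) == ["clean", "exact_half"]  # >50% excluded, strict
        assert drop == ["sixty"]


class TestScan:
    @pytest.fixture(scope="class")
    def burst_scan(self, gammarid_tree):
        cfg = preset_config("gammarid-like", seed=77, n_genes=40,
                            gene_length_range=(180, 220),
                            bursts=(BurstSpec("g0010", "n3", 10),))
        res = simulate_dataset(cfg)
        return res, scan_bursts(gammarid_tree, res.alignments())

    def test_injected_burst_detected(self, burst_scan):
        res, scan = burst_scan
        sig = scan.significant
        assert any(c.gene_id == "g0010" and "n3" in c.run.labels
                   for c in sig)
        best = min((c for c in sig if c.gene_id == "g0010"),
                   key=lambda c: c.p_adj)
        assert best.p_adj < 0.05
        assert best.k >= 10

    def test_small_burst_not_significant(self, gammarid_tree):
        cfg = preset_config("gammarid-like", seed=78, n_genes=40,
                            gene_length_range=(180, 220),
                            bursts=(BurstSpec("g0010", "n3", 2),))
        res = simulate_dataset(cfg)
        scan = scan_bursts(gammarid_tree, res.alignments())
        assert not any(c.gene_id == "g0010" for c in scan.significant)

    def test_candidate_invariants(self, burst_scan):
        _, scan = burst_scan
        for c in scan.candidates:
            assert 0.0 <= c.p_raw <= c.p_adj <= 1.0 + 1e-12
            if c.run.length > 0 and c.n_sites > 0 and not c.no_rate_signal:
                assert c.lam > 0
            assert c.k == math.floor(c.nd_raw)
        adj = [c.p_adj for c in scan.candidates]
        assert adj == sorted(adj)

    def test_synonymous_control_clean(self, burst_scan):
        _, scan = burst_scan
        assert scan.syn_candidates == []

    def test_table1_report_shape(self, burst_scan):
        _, scan = burst_scan
        table = scan.table1()
        assert list(table.columns) == [
            "edge_run", "edge_ds", "gene", "nonsyn_substitutions",
            "syn_substitutions", "gene_dnds_excluding_burst", "adjusted_p"]
        assert (table["gene"] == "g0010").any()

    def test_gene_dnds_excludes_burst_run(self, burst_scan):
        """The reported dN/dS of the burst gene must not be inflated by the
        injected substitutions themselves (neutral elsewhere => ~1)."""
        _, scan = burst_scan
        row = min((c for c in scan.significant if c.gene_id == "g0010"),
                  key=lambda c: c.p_adj)
        assert 0.3 < c_ratio(row) < 2.5

    def test_scan_without_short_edges(self):
        tree = bs.parse_newick("((A:0.02,B:0.02)x:0.03,(C:0.02,D:0.02)"
                               "y:0.03)r;")
        aln = CodonAlignment("g", {t: "ATGTTTGGG" for t in "ABCD"})
        result = scan_bursts(tree, {"g": aln})
        assert result.candidates == []
        assert any("no internal edge runs" in w for w in result.warnings)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            ScanConfig(min_posterior=1.2)
        with pytest.raises(ValueError):
            ScanConfig(rounding="banker")


def c_ratio(candidate):
    return candidate.gene_dnds_excluding_run
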