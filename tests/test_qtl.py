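import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fusemap.qtl import (
    call_qtl_regions,
    fisher_two_sided,
    fisher_window_scan,
    permutation_threshold,
    qc_filter_panel,
)


class TestFisher:
    def test_perfect_association_table(self):
        # all 20!/(10!10!) = 184756 tables with these margins; the two
        # extreme ones are the only ones as improbable as observed
        assert fisher_two_sided([[10, 0], [0, 10]]) == pytest.approx(2 / 184756)

    def test_perfect_independence(self):
        assert fisher_two_sided([[5, 5], [5, 5]]) == 1.0

    def test_degenerate_margin_is_one(self):
        assert fisher_two_sided([[7, 3], [0, 0]]) == 1.0
        assert fisher_two_sided([[7, 0], [3, 0]]) == 1.0

    @settings(max_examples=150, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_scipy_reference(self, cells):
        a, b, c, d = cells
        table = [[a, b], [c, d]]
        ours = fisher_two_sided(table)
        ref = stats.fisher_exact(table, alternative="two-sided")[1]
        assert ours == pytest.approx(ref, rel=1e-9, abs=1e-12)

    def test_invalid_table_rejected(self):
        with pytest.raises(ValueError):
            fisher_two_sided([[1, -1], [0, 2]])


class TestScan:
    def test_scan_counts_and_degenerate_flags(self, call_matrix):
        mat = call_matrix.copy()
        mat[("c1", 300001)] = "absent"  # fixed margin: no introgression variation
        phen = pd.Series([True, True, False, False, True, False], index=mat.index)
        scan = fisher_window_scan(mat, phen)
        assert len(scan) == mat.shape[1]
        row = scan.loc[(scan.chrom == "c1") & (scan.start == 300001)].iloc[0]
        assert row["degenerate"] and row["p"] == 1.0

    def test_missing_calls_excluded_pairwise(self, call_matrix):
        phen = pd.Series([True, True, False, False, True, False], index=call_matrix.index)
        scan = fisher_window_scan(call_matrix, phen)
        row = scan.loc[(scan.chrom == "c2") & (scan.start == 100001)].iloc[0]
        assert row["n"] == 5  # one individual missing at this window

    def test_scan_matches_direct_fisher(self, call_matrix):
        phen = pd.Series([True, False, True, False, True, False], index=call_matrix.index)
        scan = fisher_window_scan(call_matrix, phen)
        col = call_matrix[("c1", 1)]
        valid = col != "missing"
        g = (col == "present")[valid]
        ph = phen[valid]
        table = [
            [int((g & ph).sum()), int((g & ~ph).sum())],
            [int((~g & ph).sum()), int((~g & ~ph).sum())],
        ]
        assert scan.loc[(scan.chrom == "c1") & (scan.start == 1), "p"].iloc[0] == pytest.approx(
            fisher_two_sided(table)
        )


class TestPermutationThreshold:
    def _panel(self, rng, n=40, n_windows=25):
        cols = pd.MultiIndex.from_tuples([("c1", 1 + k * 100_000) for k in range(n_windows)])
        geno = rng.random((n, n_windows)) < 0.5
        calls = pd.DataFrame(np.where(geno, "present", "absent"), columns=cols)
        calls.index = [f"i{k}" for k in range(n)]
        phen = pd.Series(rng.random(n) < 0.5, index=calls.index)
        return calls, phen

    def test_threshold_is_alpha_quantile_of_minima(self, rng):
        calls, phen = self._panel(rng)
        thr, minima = permutation_threshold(calls, phen, n_perm=200, alpha=0.05, seed=3)
        assert thr == pytest.approx(np.sort(minima)[int(0.05 * 200) - 1])

    def test_deterministic_under_seed(self, rng):
        calls, phen = self._panel(rng)
        t1, _ = permutation_threshold(calls, phen, n_perm=150, alpha=0.05, seed=9)
        t2, _ = permutation_threshold(calls, phen, n_perm=150, alpha=0.05, seed=9)
        assert t1 == t2

    def test_invariant_to_individual_relabeling_and_constant_window(self, rng):
        calls, phen = self._panel(rng)
        t1, _ = permutation_threshold(calls, phen, n_perm=120, alpha=0.05, seed=5)
        perm = rng.permutation(len(calls))
        calls2 = calls.iloc[perm]
        phen2 = phen.iloc[perm]
        t2, _ = permutation_threshold(calls2, phen2, n_perm=120, alpha=0.05, seed=5)
        assert t1 == pytest.approx(t2)
        # adding an all-present window cannot change the minima
        calls3 = calls.copy()
        calls3[("c1", 99_000_001)] = "present"
        t3, _ = permutation_threshold(calls3, phen, n_perm=120, alpha=0.05, seed=5)
        assert t1 == pytest.approx(t3)

    def test_degenerate_phenotypes_rejected(self, rng):
        calls, phen = self._panel(rng)
        with pytest.raises(ValueError):
            permutation_threshold(calls, pd.Series(True, index=calls.index), n_perm=100)
        with pytest.raises(ValueError):
            permutation_threshold(calls, phen, n_perm=50)


class TestQcFilter:
    def _phen(self):
        return pd.DataFrame(
            {
                "n_progeny": [25, 25, 3, 0],
                "normal_fraction": [0.9, 0.5, 1.0, 0.0],
                "has_male_siblings": [True, True, True, True],
            },
            index=["h1", "h2", "h3", "h4"],
        )

    def _calls(self, index):
        cols = pd.MultiIndex.from_tuples([("ChrI", 1), ("ChrX", 1)], names=["chrom", "start"])
        return pd.DataFrame("present", index=index, columns=cols)

    def test_putative_self_progeny_removed(self):
        phen, calls = qc_filter_panel(self._phen(), self._calls(["h1", "h2", "h3", "h4"]), "hermaphrodite")
        assert "h1" not in phen.index  # >20 progeny and >80% normal
        assert "h2" in phen.index  # both conditions required

    def test_chrx_windows_dropped_in_male_modes(self):
        phen, calls = qc_filter_panel(self._phen(), self._calls(["h1", "h2", "h3", "h4"]), "male")
        assert "ChrX" not in calls.columns.get_level_values(0)
        phen, calls = qc_filter_panel(self._phen(), self._calls(["h1", "h2", "h3", "h4"]), "female")
        assert "ChrX" in calls.columns.get_level_values(0)

    def test_empty_panel_rejected(self):
        phen = self._phen().iloc[:1]
        with pytest.raises(ValueError):
            qc_filter_panel(phen, self._calls(["h1"]), "hermaphrodite")


class TestQtlRegions:
    def _scan(self, ps):
        return pd.DataFrame(
            {"chrom": "c1", "start": 1 + 100_000 * np.arange(len(ps)), "p": ps}
        )

    def test_contiguous_run_merged_with_peak(self):
        scan = self._scan([0.5, 1e-4, 1e-6, 1e-3, 0.9])
        regions = call_qtl_regions(scan, threshold=0.01)
        assert len(regions) == 1
        assert regions["peak_start"].iloc[0] == 200_001
        assert regions["n_windows"].iloc[0] == 3

    def test_no_significant_windows(self):
        assert call_qtl_regions(self._scan([0.5, 0.9]), 0.01).empty

    def test_gap_splits_runs(self):
        scan = self._scan([1e-4, 0.5, 1e-4])
        assert len(call_qtl_regions(scan, 0.01)) == 2
        assert len(call_qtl_regions(scan, 0.01, gap_tolerance=1)) == 1
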