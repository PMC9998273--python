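import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fusemap.genotyping import (
    SmoothingConfig,
    compute_window_ralt,
    genotype_ril_windows,
    genotype_unique_snp_windows,
    select_informative_snps,
    smooth_and_call_introgression,
)


def _variants(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "ref_count", "alt_count"])


class TestInformativeSnpFilter:
    @pytest.mark.parametrize(
        "ref,alt,kept",
        [
            (0, 50, True),  # 100% alternative, depth 50
            (2, 65, False),  # ~97% alternative
            (1, 49, True),  # exactly 98%
            (0, 5, False),  # below depth range
            (0, 300, True),  # top of depth range inclusive
            (0, 301, False),
            (0, 10, True),  # bottom of depth range inclusive
        ],
    )
    def test_alt_fraction_and_depth_rules(self, ref, alt, kept):
        panel = select_informative_snps(_variants([("c1", 100, ref, alt)]))
        assert (len(panel) == 1) is kept

    def test_output_sorted_by_position(self):
        panel = select_informative_snps(
            _variants([("c2", 5, 0, 50), ("c1", 9, 0, 50), ("c1", 2, 0, 50)])
        )
        assert list(panel["pos"]) == [2, 9, 5]

    def test_missing_depth_rejected(self):
        bad = _variants([("c1", 1, np.nan, 50)])
        with pytest.raises(ValueError):
            select_informative_snps(bad)


class TestWindowRalt:
    def test_summed_count_ratio(self):
        tab = _variants([("c1", 10, 0, 2), ("c1", 20, 1, 1), ("c1", 30, 3, 0)])
        res = compute_window_ralt(tab, window_size=1000)
        assert res["r_alt"].iloc[0] == pytest.approx(3 / 7)

    def test_all_reference_window_is_zero(self):
        tab = _variants([("c1", 10, 5, 0), ("c1", 20, 2, 0)])
        assert compute_window_ralt(tab, 1000)["r_alt"].iloc[0] == 0.0

    def test_uncovered_window_missing(self):
        tab = _variants([("c1", 10, 0, 0)])
        res = compute_window_ralt(tab, 1000, chrom_lengths={"c1": 3000})
        assert res["r_alt"].isna().all()
        assert len(res) == 3  # full grid emitted

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 5), st.integers(0, 5)), min_size=1, max_size=15))
    def test_matches_per_read_tally(self, sites):
        tab = _variants([("c1", i + 1, r, a) for i, (a, r) in enumerate(sites)])
        got = compute_window_ralt(tab, 10**6)["r_alt"].iloc[0]
        reads = [1] * sum(a for a, _ in sites) + [0] * sum(r for _, r in sites)
        if reads:
            assert got == pytest.approx(np.mean(reads))
        else:
            assert np.isnan(got)

    def test_monotone_in_alternative_count(self):
        base = _variants([("c1", 10, 3, 1), ("c1", 20, 2, 2)])
        more = _variants([("c1", 10, 3, 4), ("c1", 20, 2, 2)])
        assert (
            compute_window_ralt(more, 1000)["r_alt"].iloc[0]
            > compute_window_ralt(base, 1000)["r_alt"].iloc[0]
        )


def _windows(chrom, values, size=100_000, length=None):
    starts = np.arange(1, len(values) * size, size)
    return pd.DataFrame(
        {
            "chrom": chrom,
            "start": starts,
            "end": starts + size - 1,
            "alt": 5,
            "ref": 5,
            "n_sites": 10,
            "n_covered": 10,
            "r_alt": values,
        }
    )


class TestSmoothingAndCalls:
    def test_span_rule_four_per_mb(self):
        assert SmoothingConfig().span_for(20e6) == pytest.approx(0.2)
        assert SmoothingConfig().span_for(2e6) == 1.0  # clamped

    def test_constant_zero_all_absent(self):
        w = _windows("c1", [0.0] * 20)
        out = smooth_and_call_introgression(w, "toP")
        assert (out["call"] == "absent").all()

    def test_constant_heterozygous_level_all_present(self):
        w = _windows("c1", [0.45] * 20)
        out = smooth_and_call_introgression(w, "toP")
        assert (out["call"] == "present").all()

    def test_direction_to_e_flags_reference_material(self):
        out = smooth_and_call_introgression(_windows("c1", [0.45] * 20), "toE")
        assert (out["call"] == "present").all()
        out = smooth_and_call_introgression(_windows("c1", [0.95] * 20), "toE")
        assert (out["call"] == "absent").all()

    def test_missing_window_interpolated_inside_block(self):
        vals = [0.5] * 10 + [np.nan] + [0.5] * 10
        out = smooth_and_call_introgression(_windows("c1", vals), "toP")
        assert out["call"].iloc[10] == "present"

    def test_too_few_windows_falls_back_with_warning(self):
        w = _windows("c1", [0.0, 0.5])
        with pytest.warns(UserWarning, match="fewer than 3"):
            out = smooth_and_call_introgression(w, "toP")
        assert list(out["call"]) == ["absent", "present"]

    def test_calls_independent_of_other_individuals(self, bc1_panel, small_lengths):
        """Processing order of individuals cannot change a call."""
        from fusemap.genotyping import genotype_panel_ralt
        from fusemap.simulate import CoverageModel, simulate_allele_depths

        pos = {e: np.arange(5000, 2_000_000, 5000) for e in small_lengths}
        tables = simulate_allele_depths(
            bc1_panel[:4], pos, CoverageModel(0.3, 0.0), seed=1
        )
        _, calls_all = genotype_panel_ralt(tables, "toP", 100_000, small_lengths, chrom_col="element")
        one = {bc1_panel[2].id: tables[bc1_panel[2].id]}
        _, calls_one = genotype_panel_ralt(one, "toP", 100_000, small_lengths, chrom_col="element")
        pd.testing.assert_series_equal(
            calls_all.loc[bc1_panel[2].id], calls_one.loc[bc1_panel[2].id]
        )


class TestUniqueSnpWindows:
    def _founders(self):
        a = pd.DataFrame({"chrom": "c1", "pos": [100, 200, 300]})
        b = pd.DataFrame({"chrom": "c1", "pos": [600_000, 600_100]})
        return a, b

    def test_only_grandam_matches_is_a(self):
        a, b = self._founders()
        obs = pd.DataFrame({"chrom": "c1", "pos": [100, 200, 300]})
        g = genotype_unique_snp_windows(obs, a, b)
        assert g.loc[g.start == 1, "genotype"].iloc[0] == "A"

    def test_both_or_neither_is_undetermined(self):
        a, b = self._founders()
        both = pd.DataFrame({"chrom": "c1", "pos": [100, 600_000]})
        g = genotype_unique_snp_windows(both, a, b, window_size=10**7)
        assert g["genotype"].iloc[0] == "U"
        neither = pd.DataFrame({"chrom": "c1", "pos": [999]})
        g = genotype_unique_snp_windows(neither, a, b)
        assert (g["genotype"] == "U").all()

    def test_empty_or_overlapping_founder_sets_rejected(self):
        a, b = self._founders()
        with pytest.raises(ValueError):
            genotype_unique_snp_windows(a, a.iloc[:0], b)
        with pytest.raises(ValueError):
            genotype_unique_snp_windows(a, a, a)


class TestRilWindows:
    def _counts(self):
        rows = []
        for ind in range(8):
            for w, count in enumerate([15, 14, 16, 3, 2, 15] if ind < 6 else [0, 1, 0, 0, 0, 1]):
                rows.append({"individual": f"r{ind}", "chrom": "c1", "start": 1 + w * 100_000, "count": count})
        return pd.DataFrame(rows)

    def test_threshold_ten_pre_smoothing(self):
        g = genotype_ril_windows(self._counts())
        first = g.loc[(g.individual == "r0") & (g.start == 1)]
        assert first["initial_call"].iloc[0] == "strain"
        low = g.loc[(g.individual == "r7") & (g.start == 1)]
        assert low["initial_call"].iloc[0] == "reference"

    def test_low_frequency_windows_removed(self):
        counts = self._counts()
        # window at 600001 is strain in 1/8 individuals only
        extra = pd.DataFrame(
            [
                {"individual": f"r{k}", "chrom": "c1", "start": 600_001, "count": 15 if k == 0 else 0}
                for k in range(8)
            ]
        )
        g = genotype_ril_windows(pd.concat([counts, extra], ignore_index=True))
        assert 600_001 not in set(g["start"])

    def test_all_windows_removed_is_error(self):
        lonely = pd.DataFrame(
            [{"individual": f"r{k}", "chrom": "c1", "start": 1, "count": 15 if k == 0 else 0} for k in range(8)]
        )
        with pytest.raises(ValueError):
            genotype_ril_windows(lonely)
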