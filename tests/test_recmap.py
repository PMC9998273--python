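import numpy as np
import pandas as pd
import pytest

from fusemap.karyotype import GeneticMapModel
from fusemap.recmap import (
    GeneticMap,
    bootstrap_gene_fraction_test,
    detect_recombination_sites,
    estimate_map,
    filter_markers,
    haldane_cm,
    haldane_r,
    kosambi_cm,
    low_recombination_regions,
    marey_rate_profile,
    recombination_fertility_glm,
    riself_r,
    segregation_distortion_p,
)
from fusemap.simulate import simulate_cross_panel
from fusemap.validation import _marker_matrix_from_panel


def _bc_matrix(columns, rows):
    cols = pd.MultiIndex.from_tuples(columns, names=["chrom", "pos"])
    return pd.DataFrame(rows, columns=cols, index=[f"i{k}" for k in range(len(rows))])


class TestMapFunctions:
    def test_haldane_closed_form(self):
        assert haldane_cm(0.1) == pytest.approx(-50 * np.log(0.8))
        assert haldane_cm(0.1) == pytest.approx(11.157, abs=1e-3)

    def test_haldane_round_trip(self):
        cm = np.array([0.5, 5.0, 20.0, 70.0])
        assert np.allclose(haldane_cm(haldane_r(cm)), cm)

    def test_kosambi_below_haldane(self):
        assert kosambi_cm(0.2) < haldane_cm(0.2)

    def test_riself_correction(self):
        # observed fixation discordance 0.25 -> meiotic r = 1/6
        assert riself_r(0.25) == pytest.approx(1 / 6)


class TestEstimateMap:
    def test_error_free_equals_counting_oracle(self):
        rows = [["A", "A"]] * 90 + [["A", "B"]] * 10
        mat = _bc_matrix([("c1", 1_000_000), ("c1", 2_000_000)], rows)
        gmap = estimate_map(mat, "bc", error_prob=0.0)
        assert gmap.total_cm("c1") == pytest.approx(haldane_cm(0.1), abs=1e-6)

    def test_zero_recombinants_zero_cm(self):
        mat = _bc_matrix([("c1", 1), ("c1", 2_000_000)], [["A", "A"]] * 50)
        assert estimate_map(mat, "bc", 0.0).total_cm("c1") == 0.0

    def test_riself_mode_applies_haldane_waddington(self):
        rows = [["A", "A"]] * 75 + [["A", "B"]] * 25
        mat = _bc_matrix([("c1", 1), ("c1", 2_000_000)], rows)
        gmap = estimate_map(mat, "riself", error_prob=0.0)
        assert gmap.total_cm("c1") == pytest.approx(float(haldane_cm(1 / 6)), abs=1e-6)
        assert gmap.total_cm("c1") == pytest.approx(20.27, abs=0.01)

    def test_missing_data_bridged_by_the_chain(self):
        # middle marker unobserved for everyone: total map driven by flanks
        rows = [["A", "U", "A"]] * 90 + [["A", "U", "B"]] * 10
        mat = _bc_matrix([("c1", 1), ("c1", 500_000), ("c1", 1_000_000)], rows)
        gmap = estimate_map(mat, "bc", 0.0)
        assert gmap.total_cm("c1") == pytest.approx(haldane_cm(0.1), abs=0.2)

    def test_isolated_flips_attributed_to_genotyping_error(self):
        """A lone discordant marker inflates a no-error map but not an
        error-aware one."""
        rows = [["A"] * 9 for _ in range(100)]
        rows[0][4] = "B"  # single-individual, single-marker flip
        cols = [("c1", 100_000 * (k + 1)) for k in range(9)]
        with_err = estimate_map(_bc_matrix(cols, rows), "bc", error_prob=0.01).total_cm("c1")
        no_err = estimate_map(_bc_matrix(cols, rows), "bc", error_prob=0.0).total_cm("c1")
        assert no_err == pytest.approx(2 * haldane_cm(0.01), rel=0.05)
        assert with_err < 0.3 * no_err

    def test_cumulative_cm_non_decreasing(self, small_map, small_lengths):
        panel = simulate_cross_panel("bc1_to_P", 80, small_map, small_lengths, seed=21)
        gmap = estimate_map(_marker_matrix_from_panel(panel, small_lengths), "bc")
        for chrom in gmap.chromosomes():
            cm = gmap.table.loc[gmap.table.chrom == chrom, "cm"].to_numpy()
            assert (np.diff(cm) >= 0).all()


class TestFiltering:
    def test_segregation_distortion_removed(self):
        rng = np.random.default_rng(0)
        fair = np.where(rng.random((100, 6)) < 0.5, "A", "B").astype(object)
        fair[:, 2] = ["A"] * 95 + ["B"] * 5  # distorted marker
        cols = [("c1", 100_000 * (k + 1)) for k in range(6)]
        mat = _bc_matrix(cols, fair.tolist())
        p = segregation_distortion_p(mat)
        assert p.iloc[2] * 6 < 0.05
        filtered, log = filter_markers(mat, "bc", min_valid_markers=1)
        assert ("c1", 300_000) not in filtered.columns
        assert (log["reason"] == "segregation distortion").any()

    def test_individuals_with_too_few_valid_markers_removed(self):
        rows = [["A", "A", "A", "A"]] * 10 + [["U", "U", "U", "A"]]
        mat = _bc_matrix([("c1", k + 1) for k in range(4)], rows)
        filtered, log = filter_markers(mat, "bc", min_valid_markers=2, distortion_alpha=0.0)
        assert "i10" not in filtered.index
        assert "i10" in set(log["id"])

    def test_map_inflating_marker_dropped(self):
        """A noise marker inside a tight linkage group shrinks the map by
        more than 10 cM when dropped."""
        rng = np.random.default_rng(1)
        n = 120
        base = np.where(rng.random(n) < 0.5, "A", "B")
        rows = np.tile(base[:, None], (1, 7)).astype(object)
        rows[:, 3] = np.where(rng.random(n) < 0.5, "A", "B")  # unlinked noise
        cols = [("c1", 100_000 * (k + 1)) for k in range(7)]
        mat = _bc_matrix(cols, rows.tolist())
        filtered, log = filter_markers(mat, "bc", min_valid_markers=1, distortion_alpha=0.0)
        assert ("c1", 400_000) not in filtered.columns


class TestRateProfileAndRegions:
    def _uniform_map(self, rate_cm_per_mb=1.0, n=40, spacing=500_000):
        pos = spacing * np.arange(1, n + 1)
        cm = rate_cm_per_mb * pos / 1e6
        table = pd.DataFrame({"chrom": "c1", "pos": pos, "cm": cm - cm[0], "r_to_next": np.nan, "n_pairs": 0})
        return GeneticMap(table)

    def test_flat_map_flat_profile(self):
        profile = marey_rate_profile(self._uniform_map(1.0))
        assert np.allclose(profile.table["smoothed"], 1.0, atol=1e-6)
        assert profile.genome_average == pytest.approx(1.0)

    def test_coincident_markers_merged(self):
        gmap = self._uniform_map()
        dup = gmap.table.iloc[[5]].copy()
        gmap2 = GeneticMap(pd.concat([gmap.table, dup], ignore_index=True))
        profile = marey_rate_profile(gmap2)
        assert np.isfinite(profile.table["rate"]).all()

    def test_flat_profile_has_no_low_regions(self):
        gmap = self._uniform_map()
        profile = marey_rate_profile(gmap)
        regions = low_recombination_regions(profile, gmap)
        # smoothed == average everywhere: strict inequality -> empty
        assert regions.empty or (regions["end"] - regions["start"]).sum() < 2e6

    def test_dip_detected_with_gene_fraction(self):
        pos = 500_000 * np.arange(1, 41)
        rate = np.where((pos > 8e6) & (pos < 13e6), 0.2, 1.5)
        cm = np.concatenate([[0.0], np.cumsum(rate[:-1] * np.diff(pos) / 1e6)])
        gmap = GeneticMap(pd.DataFrame({"chrom": "c1", "pos": pos, "cm": cm, "r_to_next": np.nan, "n_pairs": 0}))
        profile = marey_rate_profile(gmap)
        genes = pd.DataFrame({"chrom": "c1", "pos": np.linspace(1e6, 19e6, 200).astype(int)})
        regions = low_recombination_regions(profile, gmap, genes=genes)
        assert len(regions) == 1
        r = regions.iloc[0]
        assert r["start"] < 9e6 and r["end"] > 12e6
        expected_frac = ((genes.pos >= r.start) & (genes.pos <= r.end)).mean()
        assert r["gene_fraction"] == pytest.approx(expected_frac)


class TestBootstrap:
    def _setup(self):
        pos = 500_000 * np.arange(1, 41)
        gmap = GeneticMap(
            pd.DataFrame({"chrom": "c1", "pos": pos, "cm": pos / 1e6, "r_to_next": np.nan, "n_pairs": 0})
        )
        regions = pd.DataFrame([{"chrom": "c1", "start": 5e6, "end": 8e6, "cm": 3.0}])
        return gmap, regions

    def test_all_genes_inside_gives_minimal_p(self):
        gmap, regions = self._setup()
        genes = pd.DataFrame({"chrom": "c1", "pos": np.linspace(5.1e6, 7.9e6, 50).astype(int)})
        p, null, obs = bootstrap_gene_fraction_test(regions, gmap, genes, {"c1": 20e6}, n_iter=200, seed=1)
        assert obs == 1.0
        assert p == pytest.approx(1 / 201)

    def test_zero_genes_rejected(self):
        gmap, regions = self._setup()
        with pytest.raises(ValueError):
            bootstrap_gene_fraction_test(regions, gmap, pd.DataFrame(columns=["chrom", "pos"]), {"c1": 20e6})

    def test_excessive_genetic_distance_rejected(self):
        gmap, regions = self._setup()
        regions = regions.assign(cm=100.0)
        genes = pd.DataFrame({"chrom": "c1", "pos": [1_000_000]})
        with pytest.raises(ValueError):
            bootstrap_gene_fraction_test(regions, gmap, genes, {"c1": 20e6}, n_iter=10)

    def test_null_fractions_near_region_share(self):
        gmap, regions = self._setup()
        rng = np.random.default_rng(3)
        genes = pd.DataFrame({"chrom": "c1", "pos": rng.integers(1, 20_000_000, 500)})
        p, null, obs = bootstrap_gene_fraction_test(regions, gmap, genes, {"c1": 20e6}, n_iter=500, seed=2)
        # 3 cM on a 1 cM/Mb map = 3 Mb of a 20 Mb genome
        assert np.mean(null) == pytest.approx(3 / 20, abs=0.02)


class TestRecombinationSites:
    def _calls(self, rows, chrom="ChrI"):
        cols = pd.MultiIndex.from_tuples(
            [(chrom, 1 + 100_000 * k) for k in range(len(rows[0]))], names=["chrom", "start"]
        )
        return pd.DataFrame(rows, columns=cols, index=[f"i{k}" for k in range(len(rows))])

    def test_single_change_at_boundary_midpoint(self):
        calls = self._calls([["A", "A", "A", "B", "B"]])
        sites, excluded = detect_recombination_sites(calls)
        assert len(sites) == 1
        assert sites["midpoint"].iloc[0] == pytest.approx((200_001 + 300_001) / 2)
        assert excluded == []

    def test_constant_calls_no_sites(self):
        sites, _ = detect_recombination_sites(self._calls([["A"] * 5]))
        assert sites.empty

    def test_change_near_fusion_breakpoint_excludes_individual(self):
        rows = [["A"] * 210 + ["B"] * 30]
        calls = self._calls(rows)
        sites, excluded = detect_recombination_sites(
            calls, fusion_chrom="ChrI", breakpoint_bp=21_050_000.0
        )
        assert excluded == ["i0"]
        assert sites.empty

    def test_trisomic_individuals_dropped_first(self):
        calls = self._calls([["A", "A", "B", "B", "B"], ["A", "B", "B", "B", "B"]])
        sites, excluded = detect_recombination_sites(calls, trisomic_ids=("i0",))
        assert excluded == ["i0"]
        assert set(sites["individual"]) == {"i1"}

    def test_missing_windows_skipped(self):
        calls = self._calls([["A", "missing", "A", "B", "B"]])
        sites, _ = detect_recombination_sites(calls)
        assert len(sites) == 1


class TestFertilityGlm:
    def test_null_slope_large_p(self, rng):
        n = 120
        sites = pd.DataFrame(
            {"individual": [f"i{k}" for k in range(n)], "chrom": "IR", "midpoint": rng.uniform(0, 1e7, n)}
        )
        phen = pd.Series(rng.random(n) < 0.5, index=sites["individual"])
        res = recombination_fertility_glm(sites, phen, ("IR", 0, 1e7))
        assert not res.separated
        assert res.p > 1e-4
        assert res.lrt >= 0

    def test_strong_effect_detected(self, rng):
        n = 150
        pos = rng.uniform(0, 1e7, n)
        prob = 1 / (1 + np.exp(0.9 * (pos / 1e6 - 5)))
        sites = pd.DataFrame({"individual": [f"i{k}" for k in range(n)], "chrom": "IR", "midpoint": pos})
        phen = pd.Series(rng.random(n) < prob, index=sites["individual"])
        res = recombination_fertility_glm(sites, phen, ("IR", 0, 1e7))
        assert res.p < 0.01
        assert res.coefficient < 0

    def test_complete_separation_flagged(self):
        pos = np.linspace(1e6, 9e6, 40)
        sites = pd.DataFrame({"individual": [f"i{k}" for k in range(40)], "chrom": "IR", "midpoint": pos})
        phen = pd.Series(pos > 5e6, index=sites["individual"])
        res = recombination_fertility_glm(sites, phen, ("IR", 0, 1e7))
        assert res.separated and res.p is None

    def test_multiple_sites_use_mean_position(self):
        sites = pd.DataFrame(
            {
                "individual": ["a", "a", "b", "c", "d"],
                "chrom": "IR",
                "midpoint": [2e6, 4e6, 5e6, 1e6, 8e6],
            }
        )
        phen = pd.Series([True, False, True, False], index=["a", "b", "c", "d"])
        res = recombination_fertility_glm(sites, phen, ("IR", 0, 1e7))
        assert res.n == 4
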