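import numpy as np
import pandas as pd
import pytest

from fusemap.karyotype import ELEMENT_NAMES, GeneticMapModel
from fusemap.simulate import (
    CoverageModel,
    PhenotypeModel,
    assign_phenotypes,
    crossover_breakpoints,
    simulate_allele_depths,
    simulate_cross_panel,
    simulate_window_coverage,
    true_window_calls,
)


def _assert_tiles(copy, length):
    assert copy[0][0] == 1 and copy[-1][1] == length
    for (s1, e1, _), (s2, e2, _) in zip(copy, copy[1:]):
        assert s2 == e1 + 1


def test_ancestry_segments_tile_every_copy(bc1_panel, small_lengths):
    for ind in bc1_panel:
        for el, copies in ind.haplotypes.items():
            for copy in copies:
                _assert_tiles(copy, small_lengths[el])


def test_obligate_mode_at_most_one_breakpoint(bc1_panel):
    for ind in bc1_panel:
        for el in ELEMENT_NAMES:
            assert len(crossover_breakpoints(ind, el)) <= 1


def test_nondisjunction_zero_gives_all_disomic(bc1_panel):
    assert all(len(i.haplotypes["IR"]) == 2 for i in bc1_panel)


def test_nondisjunction_rate_recovered(small_map, small_lengths):
    panel = simulate_cross_panel(
        "bc1_to_P", 500, small_map, small_lengths, nondisjunction_rate=0.2, seed=5
    )
    frac = np.mean([len(i.haplotypes["IR"]) == 3 for i in panel])
    half = 2.576 * np.sqrt(0.2 * 0.8 / 500)
    assert 0.2 - half < frac < 0.2 + half


def test_crossover_count_matches_map_length(small_lengths):
    """Mean breakpoints per gamete = map length in Morgans (Poisson mode)."""
    gm = GeneticMapModel.uniform(small_lengths, 80.0)
    panel = simulate_cross_panel(
        "bc1_to_P", 5000, gm, small_lengths, seed=3, crossover_mode="poisson"
    )
    for el in ("II", "X"):
        counts = [len(crossover_breakpoints(i, el)) for i in panel]
        se = np.std(counts) / np.sqrt(len(counts))
        assert abs(np.mean(counts) - 0.8) < 3 * se


def test_crossover_positions_follow_inverse_marey(small_lengths):
    """A centre-suppressed map concentrates breakpoints on the arms."""
    gm = GeneticMapModel.centre_suppressed(small_lengths, 50.0, 0.5, 0.1)
    panel = simulate_cross_panel("bc1_to_P", 3000, gm, small_lengths, seed=4)
    bps = np.array([b for i in panel for b in crossover_breakpoints(i, "II")])
    centre = (bps > 500_000) & (bps < 1_500_000)
    assert centre.mean() < 0.2  # 10% expected in the middle half


def test_homozygous_reference_site_never_alternative(small_map, small_lengths):
    panel = simulate_cross_panel("bc1_to_P", 4, small_map, small_lengths, seed=6)
    pos = {e: np.arange(10_000, 2_000_000, 100_000) for e in ELEMENT_NAMES}
    tables = simulate_allele_depths(panel, pos, CoverageModel(2.0, 0.0), seed=7)
    for ind in panel:
        t = tables[ind.id]
        for el in ELEMENT_NAMES:
            from fusemap.simulate import ancestry_dose

            sub = t.loc[t.element == el]
            dose = ancestry_dose(ind, el, sub["pos"].to_numpy(), "E")
            assert (sub.loc[dose == 0, "alt_count"] == 0).all()


def test_site_coverage_follows_poisson(small_map, small_lengths):
    panel = simulate_cross_panel("bc1_to_P", 10, small_map, small_lengths, seed=8)
    pos = {e: np.arange(5_000, 2_000_000, 5_000) for e in ELEMENT_NAMES}
    tables = simulate_allele_depths(panel, pos, CoverageModel(0.5, 0.0), seed=9)
    disomic = [i.id for i in panel if len(i.haplotypes["IR"]) == 2]
    covered = np.concatenate(
        [((tables[i]["ref_count"] + tables[i]["alt_count"]) > 0).to_numpy() for i in disomic]
    )
    expect = 1.0 - np.exp(-0.5)
    assert abs(covered.mean() - expect) < 0.01


def test_heterozygous_fraction_converges_to_half(small_lengths):
    gm = GeneticMapModel.uniform(small_lengths, 0.0)  # no crossovers: fully het
    panel = simulate_cross_panel("bc1_to_E", 2, gm, small_lengths, seed=10)
    pos = {e: np.arange(5_000, 2_000_000, 5_000) for e in ELEMENT_NAMES}
    tables = simulate_allele_depths(panel, pos, CoverageModel(30.0, 0.0), seed=11)
    t = pd.concat(tables.values())
    # backcross to E: every element one E copy + gamete copy;
    # with 0 cM the gamete is pure P or pure E per element
    frac = t["alt_count"].sum() / (t["alt_count"] + t["ref_count"]).sum()
    assert 0.4 < frac < 1.0  # sanity: dominated by het/hom-alt mixture


def test_trisomic_depth_ratio_converges_to_1_5(small_map, small_lengths):
    panel = simulate_cross_panel(
        "bc1_to_P", 60, small_map, small_lengths, nondisjunction_rate=0.5, seed=12
    )
    cov = simulate_window_coverage(panel, small_lengths, 100_000, 20.0, 0.05, seed=13)
    tri = [i.id for i in panel if len(i.haplotypes["IR"]) == 3]
    dis = [i.id for i in panel if len(i.haplotypes["IR"]) == 2]
    ir = cov.loc[cov.element == "IR"]
    ratio = ir.loc[ir.individual.isin(tri), "depth"].mean() / ir.loc[ir.individual.isin(dis), "depth"].mean()
    assert ratio == pytest.approx(1.5, rel=0.03)


def test_phenotype_limits_and_determinism(bc1_panel):
    model = PhenotypeModel(beta0=0.0, beta_qtl=0.0, beta_tri=0.0, qtl_pos=1_000_000)
    panel = assign_phenotypes(list(bc1_panel), model, seed=1)
    again = assign_phenotypes(list(bc1_panel), model, seed=1)
    assert [i.fertile for i in panel] == [i.fertile for i in again]
    assert all((i.n_progeny > 0) == i.fertile for i in panel)
    doomed = assign_phenotypes(list(bc1_panel), PhenotypeModel(beta0=-np.inf, qtl_pos=1_000_000), seed=2)
    assert not any(i.fertile for i in doomed)


def test_fertility_rate_half_at_zero_logit(small_map, small_lengths):
    panel = simulate_cross_panel("bc1_to_P", 400, small_map, small_lengths, seed=14)
    panel = assign_phenotypes(panel, PhenotypeModel(0.0, 0.0, 0.0, 0.0, qtl_pos=1_000_000), seed=15)
    rate = np.mean([i.fertile for i in panel])
    assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(400)


def test_ril_mode_produces_fixed_lines(small_map, small_lengths):
    panel = simulate_cross_panel("ril", 5, small_map, small_lengths, seed=16)
    for ind in panel:
        for el, copies in ind.haplotypes.items():
            assert copies[0] == copies[1]
            _assert_tiles(copies[0], small_lengths[el])
            assert {o for _, _, o in copies[0]} <= {"A", "B"}


def test_true_window_calls_match_segments(bc1_panel, small_lengths):
    calls = true_window_calls(bc1_panel, small_lengths, 100_000, origin="E")
    ind = bc1_panel[0]
    gamete_copy = ind.haplotypes["II"][1]
    for start in (1, 1_000_001):
        centre = start + 50_000
        seg_origin = next(o for s, e, o in gamete_copy if s <= centre <= e)
        assert calls.loc[ind.id, ("II", start)] == (seg_origin == "E")


def test_invalid_inputs_rejected(small_map, small_lengths):
    with pytest.raises(ValueError):
        simulate_cross_panel("bc1_to_P", 0, small_map, small_lengths)
    with pytest.raises(ValueError):
        simulate_cross_panel("bc1_to_P", 5, small_map, small_lengths, nondisjunction_rate=1.5)
    with pytest.raises(ValueError):
        simulate_cross_panel("outcross", 5, small_map, small_lengths)
    with pytest.raises(ValueError):
        CoverageModel(mean_depth_per_site=0.0)
    with pytest.raises(ValueError):
        CoverageModel(error_rate=0.6)
    with pytest.raises(ValueError):
        simulate_allele_depths([], {}, CoverageModel())
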