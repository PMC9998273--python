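"""End-to-end validation experiments on simulated study conditions.

Each function regenerates its inputs with the package's own simulator,
runs the corresponding pipeline stage and measures recovery of the
planted truth.  These are the package's standing quality experiments;
the test suite asserts on their outputs and ``scripts/acceptance.py``
reports them.

Problem sizes follow the simulated study design: a 6-chromosome, 120 Mb
genome (fused ChrI = IL+IR), diagnostic SNPs every 5 kb, 0.2x mean site
depth and 0.5% allele error for genotyping; n = 300 backcross panels for
QTL power; 200 null panels for family-wise error calibration; 1,000
bootstrap iterations over 100 replicate genomes for the gene-enrichment
null.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy import stats

from . import qtl
from .aneuploidy import element_ploidy_call, normalized_window_coverage
from .genotyping import genotype_panel_ralt
from .karyotype import ELEMENT_NAMES, GeneticMapModel, build_species_pair
from .kmers import canonical, chromosome_kmer_counts, select_marker_kmers
from .recmap import (
    estimate_map,
    haldane_cm,
    low_recombination_regions,
    marey_rate_profile,
    bootstrap_gene_fraction_test,
    recombination_fertility_glm,
)
from .sexchrom import classify_sex_linked_snps
from .simulate import (
    CoverageModel,
    PhenotypeModel,
    SimulatedIndividual,
    assign_phenotypes,
    breakpoint_windows,
    simulate_allele_depths,
    simulate_cross_panel,
    simulate_window_coverage,
    true_window_calls,
)

# the simulated study genome: six 20 Mb chromosomes, ChrI = IL + IR
STUDY_LENGTHS = {
    "IL": 10_000_000,
    "IR": 10_000_000,
    "II": 20_000_000,
    "III": 20_000_000,
    "IV": 20_000_000,
    "V": 20_000_000,
    "X": 20_000_000,
}
P_UNITS = [("IL", "IR"), ("II",), ("III",), ("IV",), ("V",), ("X",)]
STUDY_CM = {e: (25.0 if e in ("IL", "IR") else 50.0) for e in ELEMENT_NAMES}


def _seed(seed: int, tag: int) -> int:
    return int(np.random.SeedSequence((seed, tag)).generate_state(1)[0] % (2**31))


def study_map(lengths=None, cm=None) -> GeneticMapModel:
    return GeneticMapModel.uniform(lengths or STUDY_LENGTHS, cm or STUDY_CM)


# ---------------------------------------------------------------------------
# 1. oracle equivalence


def _ralt_oracle(sites: list[tuple[int, int]]) -> float:
    """Per-read tally: walk every read of every site and count."""
    reads = []
    for a, r in sites:
        reads += [1] * a + [0] * r
    return sum(reads) / len(reads) if reads else float("nan")


def _fisher_oracle(n: int, m: int, a: int, k: int) -> float:
    """Two-sided Fisher p by exhaustive enumeration with exact binomials."""
    k_min, k_max = max(0, a + m - n), min(a, m)
    denom = math.comb(n, a)
    probs = {j: math.comb(m, j) * math.comb(n - m, a - j) / denom for j in range(k_min, k_max + 1)}
    pk = probs[k]
    return min(1.0, sum(p for p in probs.values() if p <= pk * (1 + 1e-7)))


def _kmer_oracle(seq: str, kmer: str) -> int:
    """Count strand-collapsed occurrences by scanning with str.find."""
    total = 0
    from .kmers import reverse_complement

    targets = {kmer, reverse_complement(kmer)}
    for t in targets:
        i = seq.find(t)
        while i != -1:
            total += 1
            i = seq.find(t, i + 1)
    if kmer == reverse_complement(kmer):
        total //= 2
    return total


def oracle_equivalence(seed: int = 1) -> dict[str, float]:
    """Cross-check core estimators against independent brute-force oracles."""
    rng = np.random.default_rng(_seed(seed, 1))
    from .genotyping import compute_window_ralt

    # r_alt on 1,000 random windows
    max_diff = 0.0
    for _ in range(1000):
        n_sites = int(rng.integers(1, 20))
        sites = [(int(rng.integers(0, 6)), int(rng.integers(0, 6))) for _ in range(n_sites)]
        tab = pd.DataFrame(
            {
                "chrom": "c",
                "pos": np.arange(1, n_sites + 1),
                "ref_count": [r for _, r in sites],
                "alt_count": [a for a, _ in sites],
            }
        )
        res = compute_window_ralt(tab, window_size=10**9)
        got = float(res["r_alt"].iloc[0])
        want = _ralt_oracle(sites)
        if math.isnan(want):
            assert math.isnan(got)
        else:
            max_diff = max(max_diff, abs(got - want))

    # Fisher p for every 2x2 table with total n <= 40 (via margins x cell)
    fisher_max = 0.0
    for n in range(1, 41):
        for m in range(1, n):
            for a in range(1, n):
                k_min, k_max = max(0, a + m - n), min(a, m)
                vec = qtl._two_sided_p_vector(n, m, a)
                for k in range(k_min, k_max + 1):
                    fisher_max = max(fisher_max, abs(vec[k - k_min] - _fisher_oracle(n, m, a, k)))

    # k-mer counting on a 50 kb sequence
    from .kmers import count_kmers

    seq = "".join(rng.choice(list("ACGT"), size=50_000))
    counts = count_kmers(seq, 21)
    picks = list(counts)[:200] + [canonical("".join(rng.choice(list("ACGT"), 21))) for _ in range(20)]
    kmer_max = max(abs(counts.get(km, 0) - _kmer_oracle(seq, km)) for km in picks)

    # map estimation closed form: 10 recombinants of 100, error-free
    geno = np.full((100, 2), "A", dtype=object)
    geno[:10, 1] = "B"
    mat = pd.DataFrame(geno, columns=pd.MultiIndex.from_tuples([("c1", 1_000_000), ("c1", 2_000_000)]))
    est = estimate_map(mat, "bc", error_prob=0.0).total_cm("c1")
    closed = float(haldane_cm(0.1))

    return {
        "ralt_oracle_max_abs_diff": max_diff,
        "fisher_oracle_max_abs_diff": fisher_max,
        "kmer_oracle_max_abs_count_diff": float(kmer_max),
        "map_cm_10_of_100_recombinants": est,
        "map_cm_closed_form": closed,
    }


# ---------------------------------------------------------------------------
# 2. genotyping recovery


def genotyping_recovery(seed: int = 1, n_individuals: int = 100) -> dict[str, float]:
    """Window-call accuracy of the r_alt pipeline on a low-coverage panel.

    Study conditions: 6 x 20 Mb chromosomes, diagnostic SNP every 5 kb,
    0.2x mean site depth, 0.5% allele error; accuracy excludes windows
    containing a true crossover breakpoint.
    """
    gm = study_map()
    panel = simulate_cross_panel(
        "bc1_to_P", n_individuals, gm, STUDY_LENGTHS, seed=_seed(seed, 2), units=P_UNITS
    )
    model_p, _, sites = build_species_pair(element_lengths=STUDY_LENGTHS, seed=_seed(seed, 3))
    positions = {e: sites.loc[sites.element == e, "pos_in_element"].to_numpy() for e in STUDY_LENGTHS}
    cov = CoverageModel(mean_depth_per_site=0.2, error_rate=0.005)
    tables = simulate_allele_depths(panel, positions, cov, seed=_seed(seed, 4))
    tables = {k: model_p.to_chromosome_coords(v) for k, v in tables.items()}
    chrom_lengths = {c: model_p.chromosome_length(c) for c in model_p.chromosomes()}
    _, calls = genotype_panel_ralt(tables, "toP", 100_000, chrom_lengths)

    truth = true_window_calls(panel, STUDY_LENGTHS, 100_000, origin="E")
    remap = {c: model_p.locate(c[0], c[1])[0:2] for c in truth.columns}
    truth.columns = pd.MultiIndex.from_tuples(
        [(remap[c][0], int(remap[c][1])) for c in truth.columns]
    )
    truth = truth[calls.columns]
    bw = breakpoint_windows(panel, STUDY_LENGTHS, 100_000)
    bw = {
        ind: {(model_p.locate(e, s)[0], int(model_p.locate(e, s)[1])) for e, s in wins}
        for ind, wins in bw.items()
    }
    pred = calls == "present"
    accs = []
    for ind in truth.index:
        mask = np.array([c not in bw[ind] for c in truth.columns])
        accs.append(float((pred.loc[ind].to_numpy()[mask] == truth.loc[ind].to_numpy()[mask]).mean()))
    return {"call_accuracy_pct": 100.0 * float(np.mean(accs)), "n": n_individuals}


# ---------------------------------------------------------------------------
# 3. QTL calibration and power


def qtl_null_fwer(
    seed: int = 1, n_panels: int = 200, n_perm: int = 200, alpha: float = 0.05, n_individuals: int = 80
) -> dict[str, float]:
    """Family-wise error rate of the permutation threshold under the null."""
    lengths = {e: 3_000_000 for e in ELEMENT_NAMES}
    gm = GeneticMapModel.uniform(lengths, 50.0)
    hits = 0
    for rep in range(n_panels):
        rep_seed = _seed(seed, 10_000 + rep)
        panel = simulate_cross_panel("bc1_to_P", n_individuals, gm, lengths, seed=rep_seed, units=P_UNITS)
        truth = true_window_calls(panel, lengths, 100_000, origin="E")
        calls = truth.replace({True: "present", False: "absent"})
        rng = np.random.default_rng(rep_seed + 1)
        pheno = pd.Series(rng.random(len(panel)) < 0.5, index=calls.index)
        if pheno.all() or (~pheno).all():
            continue
        scan = qtl.fisher_window_scan(calls, pheno)
        thr, _ = qtl.permutation_threshold(calls, pheno, n_perm=n_perm, alpha=alpha, seed=rep_seed + 2)
        if (scan["p"] < thr).any():
            hits += 1
    return {"fwer": hits / n_panels, "alpha": alpha, "n_panels": n_panels}


def qtl_power(
    seed: int = 1,
    n_replicates: int = 20,
    n_individuals: int = 300,
    n_perm: int = 200,
    alpha: float = 0.05,
    locate_mb: float = 2.0,
) -> dict[str, float]:
    """Power to locate a planted sterility QTL within +/- 2 Mb.

    The planted QTL flips fertility from 0.8 (no introgression) to 0.2
    (introgressed) at a window on the fused element IR.
    """
    gm = study_map()
    qtl_pos = 6_000_000  # on IR
    model = PhenotypeModel(
        beta0=float(np.log(0.8 / 0.2)),
        beta_qtl=2 * float(np.log(0.2 / 0.8)),
        beta_tri=0.0,
        beta_rec=0.0,
        qtl_element="IR",
        qtl_pos=qtl_pos,
    )
    found = 0
    for rep in range(n_replicates):
        rep_seed = _seed(seed, 20_000 + rep)
        panel = simulate_cross_panel("bc1_to_P", n_individuals, gm, STUDY_LENGTHS, seed=rep_seed, units=P_UNITS)
        panel = assign_phenotypes(panel, model, seed=rep_seed + 1)
        truth = true_window_calls(panel, STUDY_LENGTHS, 100_000, origin="E")
        calls = truth.replace({True: "present", False: "absent"})
        pheno = pd.Series({i.id: i.n_progeny > 0 for i in panel})
        scan = qtl.fisher_window_scan(calls, pheno)
        thr, _ = qtl.permutation_threshold(calls, pheno, n_perm=n_perm, alpha=alpha, seed=rep_seed + 2)
        sig = scan.loc[scan["p"] < thr]
        near = sig.loc[
            (sig["chrom"] == "IR") & ((sig["start"] + 50_000 - qtl_pos).abs() <= locate_mb * 1e6)
        ]
        if len(near):
            found += 1
    return {"power_pct": 100.0 * found / n_replicates, "n_replicates": n_replicates}


# ---------------------------------------------------------------------------
# 4. aneuploidy


def _f1_panel(n: int = 5) -> list[SimulatedIndividual]:
    """Baseline F1-like individuals: one P and one E copy per element."""
    return [
        SimulatedIndividual(
            id=f"f1_{i}",
            role="F1",
            haplotypes={
                e: [[(1, STUDY_LENGTHS[e], "P")], [(1, STUDY_LENGTHS[e], "E")]] for e in STUDY_LENGTHS
            },
        )
        for i in range(n)
    ]


def aneuploidy_detection(
    seed: int = 1, n_individuals: int = 100, sigma: float = 0.2, nondisjunction_rate: float = 0.3
) -> dict[str, float]:
    """Sensitivity/specificity of coverage-based trisomy calls."""
    gm = study_map()
    panel = simulate_cross_panel(
        "bc1_to_P",
        n_individuals,
        gm,
        STUDY_LENGTHS,
        nondisjunction_rate=nondisjunction_rate,
        seed=_seed(seed, 30),
        units=P_UNITS,
    )
    cov = simulate_window_coverage(panel, STUDY_LENGTHS, 100_000, 20.0, sigma, seed=_seed(seed, 31))
    f1 = _f1_panel()
    f1_cov = simulate_window_coverage(f1, STUDY_LENGTHS, 100_000, 20.0, sigma, seed=_seed(seed, 32))
    norm = normalized_window_coverage(cov)
    f1_norm = normalized_window_coverage(f1_cov)
    intro = true_window_calls(panel, STUDY_LENGTHS, 100_000, origin="E")
    profiles = element_ploidy_call(norm, f1_norm, introgressed=intro)
    prof_ir = profiles.loc[profiles["element"] == "IR"].set_index("individual")
    truth = {i.id: len(i.haplotypes["IR"]) == 3 for i in panel}
    tp = fp = fn = tn = 0
    called = 0
    for ind, is_tri in truth.items():
        if ind not in prof_ir.index or prof_ir.loc[ind, "call"] == "undefined":
            continue
        called += 1
        got = prof_ir.loc[ind, "call"] == "trisomy"
        tp += got and is_tri
        fp += got and not is_tri
        fn += (not got) and is_tri
        tn += (not got) and not is_tri
    sens = 100.0 * tp / max(tp + fn, 1)
    spec = 100.0 * tn / max(tn + fp, 1)
    return {"trisomy_sensitivity_pct": sens, "trisomy_specificity_pct": spec, "n_called": called}


def nondisjunction_recovery(seed: int = 1, n_individuals: int = 500, rate: float = 0.2) -> dict[str, float]:
    """Recover the F1 nondisjunction rate from coverage-based trisomy calls."""
    gm = study_map()
    panel = simulate_cross_panel(
        "bc1_to_P", n_individuals, gm, STUDY_LENGTHS, nondisjunction_rate=rate, seed=_seed(seed, 33), units=P_UNITS
    )
    cov = simulate_window_coverage(panel, STUDY_LENGTHS, 100_000, 20.0, 0.2, seed=_seed(seed, 34))
    f1_cov = simulate_window_coverage(_f1_panel(), STUDY_LENGTHS, 100_000, 20.0, 0.2, seed=_seed(seed, 35))
    intro = true_window_calls(panel, STUDY_LENGTHS, 100_000, origin="E")
    profiles = element_ploidy_call(
        normalized_window_coverage(cov), normalized_window_coverage(f1_cov), introgressed=intro
    )
    prof_ir = profiles.loc[profiles["element"] == "IR"]
    # individuals without IR introgression carry two parental copies by
    # construction, so they count as disomic rather than dropping out
    frac = float((prof_ir["call"] == "trisomy").sum()) / n_individuals
    half = 2.576 * math.sqrt(rate * (1 - rate) / n_individuals)
    return {
        "trisomic_fraction": frac,
        "true_rate": rate,
        "binom99_lo": rate - half,
        "binom99_hi": rate + half,
        "n": n_individuals,
    }


# ---------------------------------------------------------------------------
# 5. map recovery


def _marker_matrix_from_panel(
    panel: list[SimulatedIndividual], lengths: dict[str, int], window_size: int = 100_000
) -> pd.DataFrame:
    """Error-free backcross marker matrix (gamete origin at window centres)."""
    truth = true_window_calls(panel, lengths, window_size, origin="E")
    mat = truth.replace({True: "B", False: "A"})
    # marker coordinate = window centre
    mat.columns = pd.MultiIndex.from_tuples(
        [(c, int(s) + window_size // 2) for c, s in mat.columns]
    )
    return mat


def map_recovery(seed: int = 1, n_individuals: int = 200) -> dict[str, float]:
    """Map-length, rate-integral and low-recombination-region recovery."""
    gm = study_map()
    panel = simulate_cross_panel("bc1_to_P", n_individuals, gm, STUDY_LENGTHS, seed=_seed(seed, 40))
    mat = _marker_matrix_from_panel(panel, STUDY_LENGTHS)
    est = estimate_map(mat, "bc", error_prob=0.001)
    rel_errors = []
    rel_errors_generating = []
    for el in STUDY_LENGTHS:
        # the panel's own (realized) map length: crossovers actually drawn
        n_bp = sum(len(ind.haplotypes[el][1]) - 1 for ind in panel)
        realized_cm = 100.0 * n_bp / n_individuals
        rel_errors.append(abs(est.total_cm(el) - realized_cm) / realized_cm)
        rel_errors_generating.append(abs(est.total_cm(el) - gm.total_cm(el)) / gm.total_cm(el))
    max_rel = 100.0 * float(np.max(rel_errors))

    profile = marey_rate_profile(est, span=0.2)
    integral = 0.0
    for chrom, fit in profile.fits.items():
        d = profile.table.loc[profile.table["chrom"] == chrom]
        x = d["mid"].to_numpy()
        integral += float(np.trapezoid(d["smoothed"].to_numpy(), x / 1e6))
    total = est.total_cm()
    integral_err = 100.0 * abs(integral - total) / total

    # centre-suppressed map: recover the suppressed interval
    gm2 = GeneticMapModel.centre_suppressed(STUDY_LENGTHS, STUDY_CM, centre_fraction=0.5, centre_share=0.1)
    panel2 = simulate_cross_panel("bc1_to_P", n_individuals, gm2, STUDY_LENGTHS, seed=_seed(seed, 41))
    est2 = estimate_map(_marker_matrix_from_panel(panel2, STUDY_LENGTHS), "bc", error_prob=0.001)
    profile2 = marey_rate_profile(est2, span=0.2)
    regions = low_recombination_regions(profile2, est2)
    inter = union = 0.0
    for el, L in STUDY_LENGTHS.items():
        lo, hi = 0.25 * L, 0.75 * L
        regs = regions.loc[regions["chrom"] == el]
        covered = 0.0
        reg_len = 0.0
        for _, r in regs.iterrows():
            covered += max(0.0, min(hi, r["end"]) - max(lo, r["start"]))
            reg_len += r["end"] - r["start"]
        inter += covered
        union += (hi - lo) + reg_len - covered
    jaccard = inter / union if union else 0.0
    return {
        "map_length_max_rel_error_pct": max_rel,
        "map_length_vs_generating_map_max_rel_error_pct": 100.0 * float(np.max(rel_errors_generating)),
        "rate_integral_error_pct": integral_err,
        "low_recomb_jaccard": float(jaccard),
        "n": n_individuals,
    }


# ---------------------------------------------------------------------------
# 6. bootstrap calibration


def bootstrap_calibration(
    seed: int = 1, n_replicates: int = 100, n_iter: int = 1000, n_genes: int = 2000
) -> dict[str, float]:
    """Null calibration of the genetic-distance-matched enrichment test.

    The null setting uses a homogeneous recombination rate and an
    arbitrary (non-enriched) region set: with genes placed uniformly,
    regions matched on genetic distance then carry no gene-density
    signal and the bootstrap p-value should be (super-)uniform.
    """
    lengths = {e: 20_000_000 for e in ("II", "III", "IV")}
    gm_model = GeneticMapModel.uniform(lengths, 50.0)
    # exact Marey coordinates: the calibration targets the bootstrap
    # sampler itself, so the matching scale is the known generating map
    rows = []
    for e, L in lengths.items():
        pos = np.arange(50_000, L, 100_000, dtype=float)
        for p_, c_ in zip(pos, gm_model.cm_at(e, pos)):
            rows.append({"chrom": e, "pos": p_, "cm": c_, "r_to_next": np.nan, "n_pairs": 0})
    from .recmap import GeneticMap

    est = GeneticMap(pd.DataFrame(rows))
    chrom_lengths = {e: float(L) for e, L in lengths.items()}
    # arbitrary observed regions: one central interval per element
    regions = pd.DataFrame(
        [
            {
                "chrom": e,
                "start": 0.3 * L,
                "end": 0.5 * L,
                "cm": float(est.cm_at(e, 0.5 * L) - est.cm_at(e, 0.3 * L)),
            }
            for e, L in lengths.items()
        ]
    )
    rng = np.random.default_rng(_seed(seed, 51))
    pvals = []
    for rep in range(n_replicates):
        genes = pd.DataFrame(
            {
                "chrom": rng.choice(list(lengths), size=n_genes, p=np.array(list(lengths.values())) / sum(lengths.values())),
                "pos": 0,
            }
        )
        genes["pos"] = [int(rng.integers(1, lengths[c] + 1)) for c in genes["chrom"]]
        p, _, _ = bootstrap_gene_fraction_test(
            regions, est, genes, chrom_lengths, n_iter=n_iter, seed=_seed(seed, 1000 + rep)
        )
        pvals.append(p)
    ks = stats.kstest(pvals, "uniform")

    # maximal-statistic check: all genes inside the observed regions
    inside = []
    for _, r in regions.iterrows():
        mids = np.linspace(r["start"] + 1, r["end"] - 1, 10)
        inside += [(r["chrom"], int(m)) for m in mids]
    genes_in = pd.DataFrame(inside, columns=["chrom", "pos"])
    p_max, _, _ = bootstrap_gene_fraction_test(
        regions, est, genes_in, chrom_lengths, n_iter=n_iter, seed=_seed(seed, 52)
    )
    return {
        "ks_p_uniformity": float(ks.pvalue),
        "mean_null_p": float(np.mean(pvals)),
        "planted_enrichment_p": float(p_max),
        "expected_min_p": 1.0 / (n_iter + 1),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# 7. GLM calibration and power


def glm_calibration(
    seed: int = 1, n_null: int = 400, n_power: int = 200, n_individuals: int = 100, slope: float = 0.8
) -> dict[str, float]:
    """Type-I error and power of the recombination-position logistic LRT."""
    rng = np.random.default_rng(_seed(seed, 60))
    region = ("IR", 0.0, 10_000_000.0)
    rejections = 0
    for _ in range(n_null):
        pos = rng.uniform(0, 10_000_000, size=n_individuals)
        y = rng.random(n_individuals) < 0.5
        sites = pd.DataFrame(
            {"individual": [f"i{j}" for j in range(n_individuals)], "chrom": "IR", "midpoint": pos}
        )
        phen = pd.Series(y, index=[f"i{j}" for j in range(n_individuals)])
        res = recombination_fertility_glm(sites, phen, region)
        if res.p is not None and res.p < 0.05:
            rejections += 1
    type1 = rejections / n_null

    power_hits = 0
    for _ in range(n_power):
        pos = rng.uniform(0, 10_000_000, size=n_individuals)
        lp = -slope * (pos / 1e6 - 5.0)
        y = rng.random(n_individuals) < 1.0 / (1.0 + np.exp(-lp))
        sites = pd.DataFrame(
            {"individual": [f"i{j}" for j in range(n_individuals)], "chrom": "IR", "midpoint": pos}
        )
        phen = pd.Series(y, index=[f"i{j}" for j in range(n_individuals)])
        res = recombination_fertility_glm(sites, phen, region)
        if res.p is not None and res.p < 0.01:
            power_hits += 1
    power = 100.0 * power_hits / n_power

    # complete separation must be flagged, not reported as a p-value
    pos = np.linspace(1e6, 9e6, 30)
    sep_sites = pd.DataFrame({"individual": [f"s{j}" for j in range(30)], "chrom": "IR", "midpoint": pos})
    sep_phen = pd.Series(pos > 5e6, index=[f"s{j}" for j in range(30)])
    sep = recombination_fertility_glm(sep_sites, sep_phen, region)
    return {
        "glm_type1_error": type1,
        "glm_power_pct": power,
        "separation_flagged": float(sep.separated),
        "n_null": n_null,
    }


# ---------------------------------------------------------------------------
# 8. probes and sex-linked SNPs


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def probe_recovery(seed: int = 1, n_genomes: int = 100, copies: int = 60) -> dict[str, float]:
    """Planted chromosome-specific 21-mer recovery across random genomes."""
    rng = np.random.default_rng(_seed(seed, 70))
    recovered = 0
    false_pos = 0
    for _ in range(n_genomes):
        planted = _random_seq(rng, 21)
        blocks = [planted + _random_seq(rng, 5) for _ in range(copies)]
        target1 = _random_seq(rng, 1500) + "".join(blocks) + _random_seq(rng, 1500)
        target2 = _random_seq(rng, 1500) + "".join(planted + _random_seq(rng, 5) for _ in range(copies)) + _random_seq(rng, 1500)
        g1 = {"chrA": target1, "chrB": _random_seq(rng, 3000), "chrC": _random_seq(rng, 3000)}
        g2 = {"chrA": target2, "chrB": _random_seq(rng, 3000), "chrC": _random_seq(rng, 3000)}
        idx = chromosome_kmer_counts({"g1": g1, "g2": g2}, k=21)
        sel = select_marker_kmers(idx, "chrA", {"chrA": "chrA", "chrB": "chrB", "chrC": "chrC"}, "g1", "g2")
        can = canonical(planted)
        if can in sel:
            recovered += 1
        false_pos += len(sel - {can})
    return {
        "probe_recovery_pct": 100.0 * recovered / n_genomes,
        "probe_false_positive_kmers": float(false_pos),
        "n_genomes": n_genomes,
    }


def sex_snp_recovery(
    seed: int = 1,
    n_sites: int = 150,
    n_per_sex: int = 5,
    depth: float = 10.0,
    error: float = 0.001,
) -> dict[str, float]:
    """Recovery of planted X- and Y-derived SNPs from sexed read counts.

    Each individual is sequenced at ``depth`` x per site.  At a planted
    Y-derived site males are X/Y heterozygous (reference on X) and
    females carry only reference; at a planted X-derived site the
    reference assembly holds the Y allele, so females show only the
    alternative.  Sensitivity is reported among sites passing the
    male-heterozygous base rule (the X/Y classes are defined only on
    those), alongside the unconditional rate.
    """
    rng = np.random.default_rng(_seed(seed, 80))
    rows = []
    truth = {}
    males = [f"m{j}" for j in range(n_per_sex)]
    females = [f"f{j}" for j in range(n_per_sex)]

    def reads(n_true_alt_frac: float, n_reads: int) -> tuple[int, int]:
        alt = rng.binomial(n_reads, n_true_alt_frac)
        ref = n_reads - alt
        # sequencing error: a read reports one of the three other bases,
        # only one of which is the focal alternative
        alt_err = rng.binomial(ref, error / 3.0)
        ref_err = rng.binomial(alt, error / 3.0)
        return ref - alt_err + ref_err, alt + alt_err - ref_err

    for s in range(2 * n_sites):
        kind = "Y" if s < n_sites else "X"
        truth[("chr1", s + 1)] = kind
        for ind, sex in [(m, "male") for m in males] + [(f, "female") for f in females]:
            n_reads = int(rng.poisson(depth))
            if sex == "male":
                ref, alt = reads(0.5, n_reads)
            elif kind == "Y":
                ref, alt = reads(0.0, n_reads)
            else:
                ref, alt = reads(1.0, n_reads)
            rows.append(
                {"chrom": "chr1", "pos": s + 1, "individual": ind, "sex": sex, "ref_count": ref, "alt_count": alt}
            )
    evidence = pd.DataFrame(rows)
    classes = classify_sex_linked_snps(evidence)
    classes["truth"] = [truth[(c, p)] for c, p in zip(classes["chrom"], classes["pos"])]
    male_het = classes["class"].isin(["male_heterozygous_only", "X_derived_alt", "Y_derived_alt"])
    y_sites = classes.loc[classes["truth"] == "Y"]
    x_sites = classes.loc[classes["truth"] == "X"]
    y_mh = y_sites.loc[male_het[y_sites.index]]
    x_mh = x_sites.loc[male_het[x_sites.index]]
    sens_y = 100.0 * float((y_mh["class"] == "Y_derived_alt").mean()) if len(y_mh) else 0.0
    sens_x = 100.0 * float((x_mh["class"] == "X_derived_alt").mean()) if len(x_mh) else 0.0
    confusion = int((y_sites["class"] == "X_derived_alt").sum() + (x_sites["class"] == "Y_derived_alt").sum())
    return {
        "ysnp_sensitivity_pct": sens_y,
        "xsnp_sensitivity_pct": sens_x,
        "xy_confusions": float(confusion),
        "ysnp_unconditional_sensitivity_pct": 100.0 * float((y_sites["class"] == "Y_derived_alt").mean()),
        "n_sites": 2 * n_sites,
    }
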