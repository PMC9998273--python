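# Methods

This note documents the models behind `fusemap`, the defaults and why
they were chosen, what the simulator does and does not emulate, and
the numerical choices that matter. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Coordinate conventions

All in-memory and TSV/VCF/GFF positions are 1-based inclusive; BED
files are converted to 0-based half-open at the I/O boundary only.
Window grids are anchored at position 1 and windows are non-overlapping
tilings ("sliding window" in the field's loose sense). A single
convention internally was preferred over a 0-based core with
converters because every consumed and emitted format except BED is
1-based, and double conversions are the classic off-by-one source.

## The simulated system

Seven chromosomal elements (IL, IR, II, III, IV, V, X) are shared by
two species on a common coordinate system. Species P fuses IL+IR
head-to-tail into ChrI (the breakpoint equals IL's length, 21.05 Mb at
full scale); species E fuses IR+X into ChrX*; an outgroup karyotype
keeps all seven apart. Species-diagnostic SNPs and genes are placed
uniformly at random per element (genes optionally centre-enriched via
a triangular density, mimicking holocentric nematode gene maps); both
species share the same positions, with species E carrying the
alternative base.

**Meiosis.** Each recombination unit (by default one element; fused
chromosomes can be declared units) receives crossovers from its Marey
map. Two modes:

- *obligate-single* (default): one crossover with probability
  total-cM/100, none otherwise — holocentric nematode bivalents
  typically show a single chiasma, and the mode makes map-recovery
  experiments sharp. It requires total map ≤ 100 cM per unit.
- *poisson*: crossover count ~ Poisson(total cM/100), no interference.

Crossover positions are uniform in genetic coordinate (inverse Marey).
The true count distribution and interference of the real F1 meiosis
are unknown, so both modes are exposed rather than asserting one.

**Cross designs.** `bc1_to_P` / `bc1_to_E` give one pure parental copy
plus one F1 gamete per element; with probability `nondisjunction_rate`
the F1 IR bivalent fails to disjoin and the gamete carries both IR
homologs (BC1 trisomy). `f3` gives a recombinant A/B haplotype (the
genotyped F2 meiosis) over a silent wild-type homolog. `ril` generates
selfed lines fixed for A/B mosaics via the Haldane–Waddington chain
(adjacent-locus switch probability R = 2r/(1+2r)) on a 100 kb grid.

**Sequencing.** Per diagnostic site, reads ~ Poisson(mean depth ×
copies/2) — a trisomic element gets 1.5× — and each read reports a
uniformly chosen copy's allele, flipped with probability `error_rate`
(default 0.5%). Window coverage for ploidy analysis is mean depth ×
(copies/2) × lognormal(0, σ) noise. Base-quality filtering (≥ 13) is
treated as upstream of these tables; sub-threshold reads are never
emitted.

**Phenotypes.** Fertility ~ Bernoulli(logistic(β0 + β_qtl·I + β_tri·T
+ β_rec·D)) with I = introgression at the designated QTL site, T = IR
trisomy, D = mean crossover displacement toward the element centre in
Mb. This genotype–phenotype map is artifact plumbing — the true map is
unknown — and exists so that scans and GLMs have planted truth.
Progeny counts of fertile animals are 1 + negative binomial
(mean 30, dispersion 2); only presence/absence feeds the analyses.

**Not emulated:** read-level FASTQ, alignment and mapping bias,
sequence-level inversions (ancestry is segment-level), Hi-C, and any
real linkage disequilibrium structure beyond the crossover model.
Passing tests therefore demonstrate correctness of the estimators
under the stated stochastic model, not robustness to alignment
artefacts in real data.

## Introgression genotyping

`r_alt = ΣA/Σ(A+R)` per non-overlapping 100 kb window is the ML
estimate of the alternative-allele probability; windows with no
covered site are missing. Per chromosome the track is LOESS-smoothed
with span = 4 / chromosome length (Mb), clamped to (0, 1]; missing
windows inside the covered range are predicted by the smoother,
windows outside it stay missing; chromosomes with < 3 defined windows
fall back to raw thresholding with a warning. Calls: backcross toward
the reference species — introgression where smoothed r_alt > 0.1;
reciprocal direction — introgression of reference material where
smoothed r_alt < 0.7. Exactly at a threshold the call is
"absent"/"no-introgression" (strict inequalities); both thresholds are
configuration.

**LOESS.** `fusemap._loess` is a tricube local-polynomial smoother
with q-nearest-neighbour bandwidth, no robustness iterations,
prediction at arbitrary positions and pointwise standard errors
(ribbons are ±1.96 SE). Degree 2 is the default — it is R `loess`'s
default and tracks the step-like genotype transitions of backcross
tracks much better than local lines; degree 1 matches
statsmodels' `lowess` and is available. r_alt windows enter the fit
weighted by their read totals, the natural weight for a summed-count
ratio. The smoother is hand-written because the pipeline needs
off-grid prediction and standard errors, which the one-shot library
smoothers do not expose; a unit test pins the degree-1 fit against
statsmodels.

## QTL scan

Two-sided Fisher exact tests use the point-probability rule (sum of
all tables at fixed margins whose hypergeometric probability is at
most the observed one, with the customary 1+1e−7 tie slack); a
vectorised hypergeometric implementation (cached per margin triple)
makes the permutation scan cheap, and is pinned against both
scipy.stats.fisher_exact and an exhaustive `math.comb` enumeration.
Missing calls are excluded per window (pairwise), preserving sample
size under sparse coverage; windows with a fixed margin get p = 1 and
a degeneracy flag. Permutations shuffle the phenotype vector only,
preserving genotype correlation; the genome-wide threshold is the
k-th smallest per-permutation minimum p with k = ⌊α·N⌋ (10th of 1,000
at α = 0.01). Windows strictly below the threshold are significant;
maximal runs merge into QTL intervals (gap tolerance 0) reporting the
minimum-p window as peak. Hermaphrodite-design QC drops putative
self-progeny (> 20 progeny and > 80% normal development) and
individuals without male siblings; designs without F1-male X variation
drop ChrX windows.

## Aneuploidy

Window depths are normalised to each individual's mean (exactly 1 by
construction), log2-scaled (zero-depth windows excluded from log
means), and compared to the per-window mean log2 normalised coverage
of the five matched F1 individuals. Per element, the mean difference
over the individual's *introgressed* windows calls trisomy above +0.3
and flags monosomy candidates below −0.5; both thresholds are
configuration. +0.3 is the midpoint of 0 and log2 1.5 ≈ 0.585, a
symmetric margin against noise; log base 2 is a pure offset choice.
Averaging the F1 baseline per window (not per element) was chosen as
the finer-grained option. A call needs ≥ 5 usable windows. When
estimating a nondisjunction *rate*, individuals with no IR
introgression count as disomic — they carry two parental copies by
construction — rather than dropping out of the denominator.

## Genetic maps and recombination profiles

Marker order is fixed to genomic position. Estimation is multipoint:
per chromosome a 2-state hidden-genotype chain (emission error =
`error_prob`, default 0.001) is fitted by forward–backward EM for the
per-interval transition fractions. This matters on dense marker grids:
a two-point estimator with an error floor of 2e(1−e) per interval
erases per-interval signal of comparable size, whereas the chain
attributes isolated single-marker flips to genotyping error and leaves
real (persistent) crossovers intact. At error 0 the fit reduces
exactly to recombinant counting, which is the oracle used in tests.
Fractions below 1e−7 after EM are snapped to exact 0. Selfed-line
(riself) data are fitted on the fixation-discordance scale and
converted with r = R/(2(1−R)). Haldane (default, matching the usual
mapping default) or Kosambi converts fractions to cM.

Marker filtering: (1) segregation-distortion chi-squared against 1:1
with Bonferroni correction at 0.05; (2) individuals with fewer than
201 valid markers removed; (3) iterated drop-one-marker — a marker is
removed when dropping it shortens its chromosome's map by more than
10 cM or raises the chromosome's multipoint log10-likelihood by more
than 2 (a standard LOD margin; the original rule names no baseline),
re-estimating until stable.

The Marey profile divides adjacent-marker ΔcM by ΔMb (coincident
positions merged first), LOESS span 0.2, 95% band = ±1.96 pointwise
SE. Low-recombination regions are maximal runs of inter-marker
intervals whose smoothed midpoint rate is strictly below the
genome-average rate (total cM / total Mb), with a 1e−9 relative guard
so exact equality never qualifies; bounds snap to flanking markers.

**Bootstrap gene-enrichment test.** The observed regions' total
genetic length defines the match; per iteration one region of equal
genetic distance is drawn with a uniformly random start on the
concatenated sampling domain, extended along the Marey fit, wrapping
to a fresh uniform start at chromosome/domain ends; one-tailed
p = (1 + #{null ≥ observed})/(N + 1). The domain default excludes the
observed regions (sampling "out of" them read as "from outside";
sampling from within would be self-comparison) and a whole-genome
domain is a flag. Note the test's null is exchangeability of gene
content *per genetic distance*: when recombination is suppressed in
gene-rich centres, uniformly-placed-gene genomes are genuinely
enriched under this null — the calibration experiment therefore uses
a homogeneous map, where matching genetic distance is equivalent to
matching physical length.

**Recombination sites and the fertility GLM.** A site is the midpoint
between adjacent non-missing windows of differing genotype;
individuals with a site inside the fusion-breakpoint exclusion zone
(21.05 ± 1 Mb) are dropped as possible undetected trisomics, after
dropping coverage-called trisomics. The GLM is logistic fertility ~
mean site position (Mb, raw position as covariate; individuals with
several sites in the region use their mean) restricted to individuals
with ≥ 1 site in the region; the LRT against the intercept-only model
is referred to χ²(1). Complete separation (all fitted probabilities at
0/1 or |coefficient| > 50) is flagged and no p reported.

## Probes and sex-linked SNPs

K-mers are counted strand-collapsed (canonical = lexicographic min of
a k-mer and its reverse complement; k must be odd so none is its own
reverse complement; windows containing N are skipped). FISH probes
hybridise denatured double-stranded targets, so strand-collapsed
counting is the defensible default; a stranded mode exists. The fused
chromosome is split at the breakpoint so IL and IR count as separate
units. Selection keeps k-mers with count > 50 on the target unit in
genome 1 AND > 50 on its homolog in genome 2 AND < 50 on every other
unit of both genomes (both thresholds exclusive). Occurrences of
selected k-mers merge into contigs wherever they overlap or abut, and
each contig is tiled greedily left-to-right with the longest feasible
oligo (24 bp down to 20), the next starting at most 2 bp before the
previous end — a deterministic stand-in for manual assembly-viewer
picking; the pairwise ≤ 2 bp overlap bound is checked exhaustively in
tests.

Sex-linked classification: male-heterozygous requires every male to
carry ≥ 1 read of the reference and ≥ 1 of the *same* alternative
allele (allele identity, not mere non-reference; conflicting
alternatives leave a site unclassified); X-derived additionally
requires every female alternative-only, Y-derived every female
reference-only. The per-individual minimum read count (default 1) is
configuration. Because the rule quantifies over *all* individuals, its
unconditional sensitivity is coverage-limited (Poisson zeros in any
one male fail the site); the validation reports sensitivity both
conditional on the male-heterozygous base rule — the discrimination
task the X/Y rules actually perform — and unconditionally. Coverage
ratios are per-window female/male means of per-individual normalised
coverage, flagged hemizygous-like above 1.6 and
autosome/non-degenerate-Y-like below 1.3 (configuration; the
biological signature is the two-fold bias).

## Validation problem sizes

The standing experiments (`fusemap.validation`, reported by
`scripts/acceptance.py` and asserted in `tests/test_acceptance.py`)
use: a 6-chromosome, 120 Mb genome (fused ChrI = 10+10 Mb at this
scale), SNP every 5 kb, 0.2× site depth, 0.5% error and n = 100 for
genotyping recovery (accuracy excludes windows holding a true
breakpoint, where a window-level call is undefined); 200 null panels
× 200 permutations (α = 0.05) for family-wise error and 20 panels of
n = 300 for power; 100 individuals (σ = 0.2 lognormal noise) for
trisomy calling and n = 500 at rate 0.2 for nondisjunction recovery;
n = 200 obligate-single-crossover panels for map recovery — judged
against the panel's realized crossover count, since at n = 200 the
meiotic sampling sd of map length (7–12%) exceeds the estimator's
error (< 1%), and both numbers are reported; 100 replicate genomes ×
1,000 bootstrap iterations with 2,000 genes for enrichment
calibration; 400/200 replicates at n = 100 for GLM type-I error and
power; 100 random genome pairs for probe recovery and 5+5 worms at
10× for sex-SNP recovery. These sizes were chosen to make each
experiment's sampling error small relative to its tolerance while
keeping the whole battery runnable in about a minute.

## Known limitations

- Ancestry is tracked at segment level; there is no sequence-level
  structural variation, so inversion-mediated recombination
  suppression is represented only through the Marey map itself.
- The fertility model is a convenience logistic; effect sizes are not
  calibrated to any organism.
- The multipoint EM assumes independent per-marker call errors; real
  window-call errors are autocorrelated along chromosomes.
- The bootstrap test inherits the discreteness of gene counts; its p
  is mildly conservative by the +1 correction.
- `sex_coverage_ratio` compares per-individual normalised values, so
  it needs autosomal windows in the same table to anchor the
  normalisation.
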