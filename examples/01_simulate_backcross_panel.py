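"""Simulate a BC1 backcross panel between two species with different
chromosome fusions and write its files to disk.

Species P fuses the ancestral elements IL+IR into one large chromosome;
species E fuses IR+X.  F1 hybrids backcrossed to species P transmit one
recombinant gamete per chromosome, and with some probability the IR
bivalent fails to disjoin, producing trisomic BC1 animals.
"""

from fusemap import CoverageModel, GeneticMapModel, build_species_pair, simulate_allele_depths, simulate_cross_panel
from fusemap.io import write_panel

lengths = {e: 2_000_000 for e in ("IL", "IR", "II", "III", "IV", "V", "X")}
gmap = GeneticMapModel.uniform(lengths, cm_per_element=50.0)

panel = simulate_cross_panel(
    "bc1_to_P", n=20, map_model=gmap, lengths=lengths, nondisjunction_rate=0.2, seed=1
)
model_p, model_e, sites = build_species_pair(element_lengths=lengths, seed=1)
positions = {e: sites.loc[sites.element == e, "pos_in_element"].to_numpy() for e in lengths}
depths = simulate_allele_depths(panel, positions, CoverageModel(mean_depth_per_site=0.2), seed=2)

paths = write_panel(panel, "scratch_example_panel", depth_tables=depths, contig_lengths=lengths)

n_tri = sum(len(i.haplotypes["IR"]) == 3 for i in panel)
print(f"simulated {len(panel)} BC1 individuals; {n_tri} carry three copies of element IR")
print(f"diagnostic SNPs: {len(sites)} shared sites between the species")
for name, p in paths.items():
    print(f"  wrote {name}: {p}")
# The VCF holds per-individual AD (ref,alt) read counts at every
# diagnostic site; the truth BED records the simulated ancestry segments
# the pipeline should recover.
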