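"""Design chromosome-specific FISH oligos from 21-mers shared between
two species' homologous chromosomes.

Marker 21-mers must occur more than 50 times on the target chromosome
in both genomes and fewer than 50 times on every other chromosome;
their genomic occurrences are merged into contigs and tiled with
20-24 bp oligos overlapping by at most 2 bp.
"""

import numpy as np

from fusemap.kmers import canonical, chromosome_kmer_counts, design_oligos, select_marker_kmers

rng = np.random.default_rng(40)


def rand(n):
    return "".join(rng.choice(list("ACGT"), n))


planted = rand(21)
repeat_block = "".join(planted + rand(5) for _ in range(70))
genome1 = {"chrA": rand(2000) + repeat_block + rand(2000), "chrB": rand(5000)}
genome2 = {"chrA": rand(2000) + "".join(planted + rand(5) for _ in range(65)) + rand(2000), "chrB": rand(5000)}

index = chromosome_kmer_counts({"species1": genome1, "species2": genome2}, k=21)
markers = select_marker_kmers(index, "chrA", {"chrA": "chrA", "chrB": "chrB"}, "species1", "species2")
oligos = design_oligos(markers, genome1["chrA"], "chrA", k=21)

print(f"planted 21-mer occurs 70x on chrA of species1, 65x in species2")
print(f"selected marker k-mers: {len(markers)} (planted recovered: {canonical(planted) in markers})")
print(f"designed oligos: {len(oligos)}")
for o in oligos[:3]:
    print(f"  {o.sequence} ({len(o.sequence)} bp) at chrA:{o.start}")
# Every oligo targets the planted repeat family, so a fluorophore on
# these sequences paints chrA specifically in both species.
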