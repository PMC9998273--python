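"""Classify X- and Y-derived SNPs from sexed single-worm read counts and
compute the female/male coverage ratio of a window.

A male-heterozygous site (all males show both alleles) is X-derived if
all females show only the alternative (the assembly holds the Y allele)
and Y-derived if all females show only the reference.  Hemizygous X
regions also show a two-fold female/male coverage bias.
"""

import numpy as np
import pandas as pd

from fusemap.aneuploidy import normalized_window_coverage
from fusemap.sexchrom import classify_sex_linked_snps, sex_coverage_ratio

rng = np.random.default_rng(50)
rows = []
for pos in range(1, 41):
    kind = "Y" if pos <= 20 else "X"
    for j in range(5):
        ref, alt = rng.poisson(5), rng.poisson(5)  # males: X/Y heterozygous
        rows.append(dict(chrom="cX", pos=pos, individual=f"m{j}", sex="male",
                         ref_count=max(ref, 1), alt_count=max(alt, 1)))
    for j in range(5):
        depth = rng.poisson(10)
        ref, alt = (depth, 0) if kind == "Y" else (0, depth)
        rows.append(dict(chrom="cX", pos=pos, individual=f"f{j}", sex="female",
                         ref_count=max(ref, 1) if kind == "Y" else 0,
                         alt_count=max(alt, 1) if kind == "X" else 0))
classes = classify_sex_linked_snps(pd.DataFrame(rows))
print(classes["class"].value_counts().to_string())

starts = 1 + 100_000 * np.arange(10)
fem = pd.concat(
    [pd.DataFrame(dict(individual=f"f{j}", chrom="cX", start=starts, end=starts + 99_999,
                       depth=rng.poisson(20, 10))) for j in range(3)]
)
mal = pd.concat(
    [pd.DataFrame(dict(individual=f"m{j}", chrom="cX", start=starts, end=starts + 99_999,
                       depth=rng.poisson(10, 10))) for j in range(3)]
)
# NOTE: per-individual normalisation removes absolute depth, so the
# example compares windows against each individual's own genome-wide
# mean; a real analysis includes autosomes in the same table.
ratio = sex_coverage_ratio(normalized_window_coverage(fem), normalized_window_coverage(mal))
print(ratio.head(3).round(2).to_string(index=False))
# The first 20 sites were simulated as Y-derived (females reference-
# only), the rest as X-derived (females alternative-only).
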