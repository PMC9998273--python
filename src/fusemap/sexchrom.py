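"""Neo-sex-chromosome SNP classification and sex coverage ratios.

On a young X/Y pair, sites where the reference assembly carries one
gametolog and all males are heterozygous discriminate X- from Y-derived
variation: if every female shows only the alternative allele the
alternative is X-derived (the reference holds the Y allele); if every
female shows only the reference allele the alternative is Y-derived.
Hemizygous X regions additionally show a two-fold female/male coverage
bias, while a non-degenerate neo-Y keeps the ratio near 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MALE_HET_ONLY = "male_heterozygous_only"
X_DERIVED = "X_derived_alt"
Y_DERIVED = "Y_derived_alt"
UNCLASSIFIED = "unclassified"


def classify_sex_linked_snps(
    evidence: pd.DataFrame,
    min_reads_per_individual: int = 1,
) -> pd.DataFrame:
    """Classify sites from per-individual sexed read counts.

    ``evidence`` is a long table with columns ``chrom``, ``pos``,
    ``individual``, ``sex`` ('male'/'female'), ``ref_count``,
    ``alt_count`` and optionally ``alt`` (the alternative allele; sites
    with conflicting alternative alleles across individuals are left
    unclassified).  A site is male-heterozygous when every male has both
    a reference and an alternative read; it is then X-derived if every
    female has alternative but no reference reads, Y-derived if every
    female has reference but no alternative reads.  Sites lacking a
    sexed individual with ``min_reads_per_individual`` reads on both
    sides of the comparison are unclassified.
    """
    required = {"chrom", "pos", "individual", "sex", "ref_count", "alt_count"}
    if not required <= set(evidence.columns):
        raise ValueError(f"evidence needs columns {sorted(required)}")
    rows = []
    for (chrom, pos), d in evidence.groupby(["chrom", "pos"], sort=True):
        males = d.loc[d["sex"] == "male"]
        females = d.loc[d["sex"] == "female"]
        if males.empty or females.empty:
            raise ValueError(f"site {chrom}:{pos} has no sexed coverage on one side")
        consistent_alt = True
        if "alt" in d.columns:
            alts = d.loc[d["alt_count"] > 0, "alt"].dropna().unique()
            consistent_alt = len(alts) <= 1
        t = min_reads_per_individual
        male_het = bool(
            consistent_alt
            and (males["ref_count"] >= t).all()
            and (males["alt_count"] >= t).all()
        )
        if not male_het:
            cls = UNCLASSIFIED
        elif (females["alt_count"] >= t).all() and (females["ref_count"] == 0).all():
            cls = X_DERIVED
        elif (females["ref_count"] >= t).all() and (females["alt_count"] == 0).all():
            cls = Y_DERIVED
        else:
            cls = MALE_HET_ONLY
        rows.append({"chrom": chrom, "pos": pos, "class": cls})
    return pd.DataFrame(rows)


@dataclass
class RatioConfig:
    """Flagging thresholds on the female/male coverage ratio."""

    hemizygous_min: float = 1.6  # two-fold bias expected for X against degenerate Y
    nondegenerate_max: float = 1.3


def sex_coverage_ratio(
    female_norm: pd.DataFrame,
    male_norm: pd.DataFrame,
    config: RatioConfig | None = None,
    chrom_col: str = "chrom",
) -> pd.DataFrame:
    """Per-window female/male ratio of mean normalised coverage.

    Both inputs are normalised coverage tables (see
    ``aneuploidy.normalized_window_coverage``).  Windows with zero male
    coverage get an undefined ratio and a flag.
    """
    config = config or RatioConfig()
    f = female_norm.groupby([chrom_col, "start"])["normalized"].mean()
    m = male_norm.groupby([chrom_col, "start"])["normalized"].mean()
    out = pd.DataFrame({"female": f, "male": m}).reset_index()
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio"] = np.where(out["male"] > 0, out["female"] / out["male"], np.nan)
    out["flag"] = np.select(
        [~np.isfinite(out["ratio"]), out["ratio"] > config.hemizygous_min, out["ratio"] < config.nondegenerate_max],
        ["undefined", "hemizygous_x_like", "autosome_or_nondegenerate_y_like"],
        default="intermediate",
    )
    return out
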