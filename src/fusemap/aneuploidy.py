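"""Copy-number estimation of hybrid chromosomal elements from coverage.

Sequencing depth per 100 kb window is normalised by the individual's
mean window depth, log2-scaled, and compared against the matched F1
baseline (mean over F1 individuals of the same sex and cross direction)
over the element's introgressed windows only.  A three-copy element
gains half a copy's worth of reads, so the expected log2 difference is
log2(1.5) ~= 0.585; a one-copy element sits at log2(0.5) = -1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .qtl import fisher_two_sided

TRISOMY = "trisomy"
DISOMY = "disomy"
MONOSOMY = "monosomy"


@dataclass
class PloidyConfig:
    """Calling thresholds on the mean log2 coverage difference."""

    trisomy_min_diff: float = 0.3  # midpoint of 0 and log2(1.5)
    monosomy_max_diff: float = -0.5
    min_windows: int = 5


def normalized_window_coverage(depths: pd.DataFrame) -> pd.DataFrame:
    """Normalise window depths so each individual's mean is exactly 1.

    ``depths`` is a long table (individual, element|chrom, start, end,
    depth).  Zero-depth windows are retained and flagged.
    """
    d = depths.copy()
    mean = d.groupby("individual")["depth"].transform("mean")
    if (mean == 0).any():
        bad = d.loc[mean == 0, "individual"].unique()
        raise ValueError(f"all-zero coverage for individual(s) {list(bad)}")
    d["normalized"] = d["depth"] / mean
    d["zero_depth"] = d["depth"] == 0
    return d


def _baseline_log2(f1_norm: pd.DataFrame, chrom_col: str) -> pd.Series:
    """Per-window mean log2 normalised coverage over the F1 individuals."""
    f1 = f1_norm.loc[~f1_norm["zero_depth"]].copy()
    f1["log2"] = np.log2(f1["normalized"])
    return f1.groupby([chrom_col, "start"])["log2"].mean()


def element_ploidy_call(
    bc1_norm: pd.DataFrame,
    f1_norm: pd.DataFrame,
    introgressed: pd.DataFrame | None = None,
    config: PloidyConfig | None = None,
    chrom_col: str = "element",
) -> pd.DataFrame:
    """Per-individual, per-element ploidy calls against the F1 baseline.

    Both coverage tables must be normalised (see
    :func:`normalized_window_coverage`).  ``introgressed`` optionally
    restricts the windows used per individual to its introgressed ones
    (boolean matrix individuals x (chrom, start), as produced by the
    genotyping step); the comparison is only meaningful there, since a
    backcross individual's non-introgressed windows are parental.
    Returns a table (individual, element, mean_diff, n_windows, call);
    elements with fewer than ``min_windows`` usable windows get call
    'undefined'.
    """
    config = config or PloidyConfig()
    baseline = _baseline_log2(f1_norm, chrom_col)
    rows = []
    for ind, d in bc1_norm.groupby("individual"):
        d = d.loc[~d["zero_depth"]].copy()
        d["log2"] = np.log2(d["normalized"])
        d = d.set_index([chrom_col, "start"])
        diff = d["log2"] - baseline.reindex(d.index)
        if introgressed is not None and ind in introgressed.index:
            mask = introgressed.loc[ind].reindex(d.index, fill_value=False).to_numpy(dtype=bool)
            diff = diff[mask]
        for el, vals in diff.dropna().groupby(level=0):
            n = len(vals)
            mean_diff = float(vals.mean())
            if n < config.min_windows:
                call = "undefined"
            elif mean_diff > config.trisomy_min_diff:
                call = TRISOMY
            elif mean_diff < config.monosomy_max_diff:
                call = MONOSOMY
            else:
                call = DISOMY
            rows.append({"individual": ind, "element": el, "mean_diff": mean_diff, "n_windows": n, "call": call})
    return pd.DataFrame(rows, columns=["individual", "element", "mean_diff", "n_windows", "call"])


def trisomy_phenotype_association(
    profiles: pd.DataFrame, has_progeny: pd.Series, element: str
) -> tuple[float, np.ndarray, bool]:
    """Two-sided Fisher test of {trisomy} x {progeny} for one element.

    Returns (p, 2x2 table, degenerate flag).  Table rows are trisomy
    yes/no, columns progeny yes/no.
    """
    prof = profiles.loc[(profiles["element"] == element) & (profiles["call"] != "undefined")]
    tri = prof.set_index("individual")["call"] == TRISOMY
    common = tri.index.intersection(has_progeny.index)
    tri = tri.loc[common]
    phen = has_progeny.loc[common].astype(bool)
    if tri.sum() == 0 or (~tri).sum() == 0:
        raise ValueError("need at least one trisomic and one disomic individual")
    table = np.array(
        [
            [int((tri & phen).sum()), int((tri & ~phen).sum())],
            [int((~tri & phen).sum()), int((~tri & ~phen).sum())],
        ]
    )
    degenerate = table[:, 0].sum() == 0 or table[:, 1].sum() == 0
    p = 1.0 if degenerate else fisher_two_sided(table)
    return p, table, bool(degenerate)
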