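"""Window-level introgression genotyping from low-coverage allele depths.

The core estimator pools reads over all informative (species-diagnostic)
sites in a non-overlapping window:

    r_alt = sum(A) / sum(A + R)

where A and R are alternative- and reference-allele read counts.  r_alt
is the maximum-likelihood estimate of the per-site alternative-allele
probability, so homozygous-reference material sits near 0, heterozygous
introgressions near 0.5 and homozygous-alternative material near 1.
Per-chromosome LOESS smoothing (span = 4 / chromosome length in Mb)
precedes categorical calling against empirically placed thresholds: in a
backcross to the reference species, smoothed values above 0.1 mark an
introgression; in the reciprocal backcross, values below 0.7 do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._loess import loess_fit

CALL_PRESENT = "present"
CALL_ABSENT = "absent"
CALL_MISSING = "missing"


@dataclass
class SmoothingConfig:
    """LOESS spans and call thresholds for introgression genotyping."""

    span_per_mb: float = 4.0  # span = span_per_mb / chromosome length (Mb)
    threshold_to_p: float = 0.1
    threshold_to_e: float = 0.7

    def span_for(self, chrom_length_bp: float) -> float:
        span = self.span_per_mb / (chrom_length_bp / 1e6)
        return float(min(max(span, 1e-6), 1.0))


def select_informative_snps(
    variants: pd.DataFrame,
    min_alt_fraction: float = 0.98,
    depth_range: tuple[int, int] = (10, 300),
) -> pd.DataFrame:
    """Filter pooled variant calls to species-diagnostic SNPs.

    ``variants`` needs columns ``chrom``, ``pos``, ``ref_count``,
    ``alt_count``.  Sites are kept when the alternative-allele fraction
    is at least ``min_alt_fraction`` and total depth lies inside
    ``depth_range`` (inclusive on both ends).
    """
    required = {"chrom", "pos", "ref_count", "alt_count"}
    if not required <= set(variants.columns):
        raise ValueError(f"variant table must have columns {sorted(required)}")
    depth = variants["ref_count"] + variants["alt_count"]
    if depth.isna().any():
        raise ValueError("variant records without depth information")
    with np.errstate(invalid="ignore"):
        frac = np.where(depth > 0, variants["alt_count"] / depth, 0.0)
    lo, hi = depth_range
    keep = (frac >= min_alt_fraction) & (depth >= lo) & (depth <= hi)
    panel = variants.loc[keep].sort_values(["chrom", "pos"]).reset_index(drop=True)
    return panel


def assign_windows(pos: np.ndarray, window_size: int) -> np.ndarray:
    """1-based window start for each position (grid anchored at 1)."""
    pos = np.asarray(pos, dtype=np.int64)
    return ((pos - 1) // window_size) * window_size + 1


def compute_window_ralt(
    table: pd.DataFrame,
    window_size: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    chrom_col: str = "chrom",
) -> pd.DataFrame:
    """Per-window r_alt for one individual's allele-depth table.

    ``table`` needs columns (``chrom``|``element``), ``pos``,
    ``ref_count``, ``alt_count``, already restricted to informative
    sites.  Windows with zero covered sites get NaN r_alt.  When
    ``chrom_lengths`` is given, the full window grid of every chromosome
    is emitted (so uncovered windows appear as missing rather than being
    silently absent).
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    tab = table.rename(columns={"element": "chrom"}) if chrom_col == "element" else table
    tab = tab.assign(
        start=assign_windows(tab["pos"].to_numpy(), window_size),
        covered=(tab["ref_count"] + tab["alt_count"] > 0).astype(int),
    )
    agg = (
        tab.groupby(["chrom", "start"], sort=True)
        .agg(
            alt=("alt_count", "sum"),
            ref=("ref_count", "sum"),
            n_sites=("pos", "size"),
            n_covered=("covered", "sum"),
        )
        .reset_index()
    )
    if chrom_lengths is not None:
        full = []
        for chrom, L in chrom_lengths.items():
            starts = np.arange(1, L + 1, window_size)
            full.append(pd.DataFrame({"chrom": chrom, "start": starts}))
        grid = pd.concat(full, ignore_index=True)
        agg = grid.merge(agg, on=["chrom", "start"], how="left")
        agg[["alt", "ref", "n_sites", "n_covered"]] = (
            agg[["alt", "ref", "n_sites", "n_covered"]].fillna(0).astype(int)
        )
    total = agg["alt"] + agg["ref"]
    with np.errstate(invalid="ignore", divide="ignore"):
        agg["r_alt"] = np.where(total > 0, agg["alt"] / total, np.nan)
    agg["end"] = agg["start"] + window_size - 1
    if chrom_lengths is not None:
        agg["end"] = [
            min(e, chrom_lengths[c]) for e, c in zip(agg["end"], agg["chrom"])
        ]
    return agg[["chrom", "start", "end", "alt", "ref", "n_sites", "n_covered", "r_alt"]]


def smooth_and_call_introgression(
    windows: pd.DataFrame,
    direction: str,
    config: SmoothingConfig | None = None,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """LOESS-smooth r_alt per chromosome and call introgression windows.

    ``direction`` is ``"toP"`` (backcross to the reference species;
    introgression where smoothed r_alt > 0.1) or ``"toE"`` (reciprocal
    backcross; introgression of reference material where smoothed
    r_alt < 0.7).  Missing windows inside the covered range are
    interpolated by the smoother; windows outside it stay missing.
    Chromosomes with fewer than 3 defined windows fall back to raw
    thresholding with a warning.
    """
    if direction not in ("toP", "toE"):
        raise ValueError("direction must be 'toP' or 'toE'")
    config = config or SmoothingConfig()
    out = []
    for chrom, d in windows.groupby("chrom", sort=False):
        d = d.sort_values("start").copy()
        length = chrom_lengths[chrom] if chrom_lengths else int(d["end"].max())
        centre = (d["start"].to_numpy() + d["end"].to_numpy()) / 2.0
        defined = np.isfinite(d["r_alt"].to_numpy())
        smoothed = np.full(len(d), np.nan)
        if defined.sum() >= 3:
            # each window's r_alt is a summed-count ratio: weight by reads
            reads = (d["alt"] + d["ref"]).to_numpy(dtype=float)
            fit = loess_fit(
                centre[defined],
                d["r_alt"].to_numpy()[defined],
                config.span_for(length),
                weights=reads[defined],
            )
            inside = (centre >= centre[defined].min()) & (centre <= centre[defined].max())
            smoothed[inside] = np.clip(fit.predict(centre[inside]), 0.0, 1.0)
        else:
            warnings.warn(f"{chrom}: fewer than 3 defined windows; raw-threshold fallback")
            smoothed[defined] = d["r_alt"].to_numpy()[defined]
        d["smoothed_r_alt"] = smoothed
        if direction == "toP":
            call = np.where(smoothed > config.threshold_to_p, CALL_PRESENT, CALL_ABSENT)
        else:
            call = np.where(smoothed < config.threshold_to_e, CALL_PRESENT, CALL_ABSENT)
        call = np.where(np.isfinite(smoothed), call, CALL_MISSING)
        d["call"] = call
        out.append(d)
    return pd.concat(out, ignore_index=True)


def genotype_panel_ralt(
    tables: dict[str, pd.DataFrame],
    direction: str,
    window_size: int = 100_000,
    chrom_lengths: dict[str, int] | None = None,
    config: SmoothingConfig | None = None,
    chrom_col: str = "chrom",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Genotype a whole panel; returns (r_alt matrix, call matrix).

    Both matrices are individuals x (chrom, start) window MultiIndex.
    """
    ralt_rows, call_rows = {}, {}
    index = None
    for ind_id in sorted(tables):
        w = compute_window_ralt(tables[ind_id], window_size, chrom_lengths, chrom_col=chrom_col)
        called = smooth_and_call_introgression(w, direction, config, chrom_lengths)
        idx = pd.MultiIndex.from_frame(called[["chrom", "start"]])
        if index is None:
            index = idx
        ralt_rows[ind_id] = pd.Series(called["r_alt"].to_numpy(), index=idx)
        call_rows[ind_id] = pd.Series(called["call"].to_numpy(), index=idx)
    return pd.DataFrame(ralt_rows).T, pd.DataFrame(call_rows).T


def genotype_unique_snp_windows(
    observed: pd.DataFrame,
    grandam_sites: pd.DataFrame,
    grandsire_sites: pd.DataFrame,
    window_size: int = 500_000,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """F3 window genotypes from grandparent-unique SNPs.

    ``observed`` holds the SNPs seen in one F3 individual (columns
    ``chrom``, ``pos``); the two site tables hold the founder-unique SNP
    positions.  A window is genotype A when it contains only
    grandam-unique matches, B when only grandsire-unique, U otherwise
    (both or neither).
    """
    for name, d in (("grandam", grandam_sites), ("grandsire", grandsire_sites)):
        if d.empty:
            raise ValueError(f"empty unique-SNP set for {name}")
    key_a = set(map(tuple, grandam_sites[["chrom", "pos"]].itertuples(index=False)))
    key_b = set(map(tuple, grandsire_sites[["chrom", "pos"]].itertuples(index=False)))
    if key_a & key_b:
        raise ValueError("grandparent-unique SNP sets overlap")
    obs = observed.copy()
    keys = list(map(tuple, obs[["chrom", "pos"]].itertuples(index=False)))
    obs["from_a"] = [k in key_a for k in keys]
    obs["from_b"] = [k in key_b for k in keys]
    obs["start"] = assign_windows(obs["pos"].to_numpy(), window_size)
    g = obs.groupby(["chrom", "start"]).agg(n_a=("from_a", "sum"), n_b=("from_b", "sum")).reset_index()
    if chrom_lengths is not None:
        grid = pd.concat(
            [
                pd.DataFrame({"chrom": c, "start": np.arange(1, L + 1, window_size)})
                for c, L in chrom_lengths.items()
            ],
            ignore_index=True,
        )
        g = grid.merge(g, on=["chrom", "start"], how="left").fillna({"n_a": 0, "n_b": 0})
    g["genotype"] = np.select(
        [(g["n_a"] > 0) & (g["n_b"] == 0), (g["n_b"] > 0) & (g["n_a"] == 0)],
        ["A", "B"],
        default="U",
    )
    return g


def genotype_ril_windows(
    counts: pd.DataFrame,
    window_size: int = 100_000,
    count_threshold: int = 10,
    min_panel_frequency: float = 0.25,
    span: float = 0.1,
    chrom_lengths: dict[str, int] | None = None,
) -> pd.DataFrame:
    """RIL window genotypes from strain-specific SNP counts.

    ``counts`` is a long table (``individual``, ``chrom``, ``start``,
    ``count``) of strain-specific SNP observations per window.  Initial
    calls are strain-homozygote when count > ``count_threshold``;
    windows whose panel-wide strain-allele frequency is <=
    ``min_panel_frequency`` are removed; the counts are then
    LOESS-smoothed along each chromosome (span ``span``) and calls
    redetermined from the predicted values.  Returns a long table with
    ``initial_call``, ``smoothed_count`` and ``call`` ('strain' or
    'reference'); removed windows are absent.
    """
    d = counts.copy()
    d["initial_call"] = np.where(d["count"] > count_threshold, "strain", "reference")
    freq = d.groupby(["chrom", "start"])["initial_call"].apply(lambda s: float((s == "strain").mean()))
    keep = freq[freq > min_panel_frequency].index
    d = d.set_index(["chrom", "start"]).loc[d.set_index(["chrom", "start"]).index.isin(keep)].reset_index()
    if d.empty:
        raise ValueError("all windows removed by the panel-frequency filter")
    out = []
    for (ind, chrom), grp in d.groupby(["individual", "chrom"], sort=False):
        grp = grp.sort_values("start").copy()
        x = grp["start"].to_numpy(dtype=float)
        y = grp["count"].to_numpy(dtype=float)
        if len(grp) >= 3:
            grp["smoothed_count"] = loess_fit(x, y, span=max(span, 3.0 / len(grp))).predict(x)
        else:
            grp["smoothed_count"] = y
        out.append(grp)
    res = pd.concat(out, ignore_index=True)
    res["call"] = np.where(res["smoothed_count"] > count_threshold, "strain", "reference")
    return res
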