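"""Genetic maps, Marey profiles, low-recombination regions and the
recombination–sterility association.

Maps are estimated from ordered marker matrices (marker order fixed to
genomic position, as appropriate for chromosome-level assemblies) by
two-point maximum likelihood on adjacent markers with a genotyping-error
probability, then converted to cM with the Haldane (default) or Kosambi
map function.  Recombinant-inbred (selfed) data are first corrected from
fixation discordance R to the meiotic recombination fraction
r = R / (2(1 - R)).  The Marey map (cM against Mb) yields local
recombination rates whose LOESS fit defines low-recombination regions
(smoothed rate below the genome average); gene enrichment of those
regions is tested by bootstrap sampling of genomic regions matched on
genetic distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._loess import LoessFit, loess_fit

A, B, U = "A", "B", "U"


# ---------------------------------------------------------------------------
# map functions

def haldane_cm(r) -> np.ndarray:
    """Haldane map distance (cM) for recombination fraction r."""
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.4999999)
    return -50.0 * np.log(1.0 - 2.0 * r)


def kosambi_cm(r) -> np.ndarray:
    r = np.clip(np.asarray(r, dtype=float), 0.0, 0.4999999)
    return 25.0 * np.log((1.0 + 2.0 * r) / (1.0 - 2.0 * r))


def haldane_r(cm) -> np.ndarray:
    """Inverse Haldane: recombination fraction for a map distance in cM."""
    return 0.5 * (1.0 - np.exp(-np.asarray(cm, dtype=float) / 50.0))


_MAP_FUNCTIONS = {"haldane": haldane_cm, "kosambi": kosambi_cm}


def riself_r(big_r) -> np.ndarray:
    """Haldane–Waddington correction: fixation discordance R -> meiotic r."""
    big_r = np.clip(np.asarray(big_r, dtype=float), 0.0, 0.65)
    return np.clip(big_r / (2.0 * (1.0 - big_r)), 0.0, 0.4999)


# ---------------------------------------------------------------------------
# marker matrices and filtering


def marker_positions(matrix: pd.DataFrame) -> pd.DataFrame:
    """(chrom, pos) frame from a marker matrix's MultiIndex columns."""
    return pd.DataFrame(
        {"chrom": matrix.columns.get_level_values(0), "pos": matrix.columns.get_level_values(1)}
    )


def _pairwise_discordance(x: np.ndarray, y: np.ndarray) -> tuple[int, int]:
    """(number of co-observed pairs, number discordant) for two markers."""
    valid = (x != U) & (y != U)
    n = int(valid.sum())
    disc = int((x[valid] != y[valid]).sum())
    return n, disc


def segregation_distortion_p(matrix: pd.DataFrame) -> pd.Series:
    """Chi-squared p for 1:1 A:B segregation per marker."""
    arr = matrix.to_numpy()
    n_a = (arr == A).sum(axis=0)
    n_b = (arr == B).sum(axis=0)
    tot = n_a + n_b
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(tot > 0, (n_a - n_b) ** 2 / np.maximum(tot, 1), 0.0)
    p = stats.chi2.sf(chi2, df=1)
    return pd.Series(p, index=matrix.columns)


def filter_markers(
    matrix: pd.DataFrame,
    cross_type: str = "bc",
    min_valid_markers: int = 201,
    distortion_alpha: float = 0.05,
    shrink_cm: float = 10.0,
    lod_drop: float = 2.0,
    error_prob: float = 0.001,
    map_function: str = "haldane",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """The study's marker/individual filtering cascade.

    1. markers failing a Bonferroni-corrected 1:1 segregation chi-squared
       test (p x n_markers < ``distortion_alpha``) are removed;
    2. individuals with fewer than ``min_valid_markers`` non-missing
       markers are removed;
    3. iteratively, a marker is removed (and the map re-estimated) when
       dropping it shortens its chromosome map by more than ``shrink_cm``
       cM or improves the map log10-likelihood by more than ``lod_drop``.

    Returns (filtered matrix, removal log).
    """
    if matrix.shape[0] < 2 or matrix.shape[1] < 2:
        raise ValueError("need at least 2 individuals and 2 markers")
    log = []
    p = segregation_distortion_p(matrix)
    distorted = p * matrix.shape[1] < distortion_alpha
    for col in matrix.columns[distorted]:
        log.append({"kind": "marker", "id": col, "reason": "segregation distortion"})
    mat = matrix.loc[:, ~distorted]

    valid = (mat != U).sum(axis=1)
    drop_ind = valid < min_valid_markers
    for ind in mat.index[drop_ind]:
        log.append({"kind": "individual", "id": ind, "reason": f"{int(valid[ind])} valid markers"})
    mat = mat.loc[~drop_ind]
    if mat.empty or mat.shape[1] == 0:
        raise ValueError("everything filtered out")

    # step 3: drop-one-marker until stable, chromosome by chromosome
    changed = True
    while changed:
        changed = False
        gmap = estimate_map(mat, cross_type, error_prob, map_function)
        for chrom in gmap.table["chrom"].unique():
            cols = [c for c in mat.columns if c[0] == chrom]
            if len(cols) <= 2:
                continue
            base = gmap.total_cm(chrom)
            base_ll = _chromosome_log10_likelihood(mat[cols], cross_type, error_prob)
            best_col, best_score = None, -np.inf
            for col in cols:
                sub_cols = [c for c in cols if c != col]
                sub = estimate_map(mat[sub_cols], cross_type, error_prob, map_function)
                shrink = base - sub.total_cm(chrom)
                ll = _chromosome_log10_likelihood(mat[sub_cols], cross_type, error_prob)
                # per-interval-pair likelihoods are not nested; compare per
                # informative meiosis to stay scale-free
                gain = ll / max(len(sub_cols) - 1, 1) - base_ll / (len(cols) - 1)
                if shrink > shrink_cm or gain * (len(cols) - 1) > lod_drop:
                    score = max(shrink, gain * (len(cols) - 1))
                    if score > best_score:
                        best_col, best_score = col, score
            if best_col is not None:
                log.append({"kind": "marker", "id": best_col, "reason": f"drop-one score {best_score:.1f}"})
                mat = mat.drop(columns=[best_col])
                changed = True
    return mat, pd.DataFrame(log, columns=["kind", "id", "reason"])


def _hmm_em_fractions(
    obs: np.ndarray, r_init: np.ndarray, error_prob: float, n_iter: int = 30, tol: float = 1e-6
) -> tuple[np.ndarray, float]:
    """EM for per-interval transition fractions of a 2-state genotype chain.

    ``obs`` is individuals x markers coded 0 (A), 1 (B), -1 (missing).
    Emissions: the observed call matches the latent genotype with
    probability 1 - error_prob.  This is the multipoint treatment that
    lets isolated single-marker flips be explained as genotyping error
    instead of double crossovers — the behaviour expected of a mapping
    routine run with a small ``error.prob``.  Returns the fitted
    transition fractions and the final log10-likelihood.
    """
    n_ind, n_mark = obs.shape
    e = max(error_prob, 0.0)
    # emission probabilities per individual/marker/state
    em = np.ones((n_ind, n_mark, 2))
    for s in (0, 1):
        match = obs == s
        mismatch = (obs >= 0) & ~match
        em[:, :, s][match] = 1.0 - e
        em[:, :, s][mismatch] = e
    r = np.clip(np.asarray(r_init, dtype=float), 1e-8, 0.4999)
    ll_old = -np.inf
    ll = ll_old
    for _ in range(n_iter):
        # forward-backward, scaled, vectorised over individuals
        alpha = np.empty((n_ind, n_mark, 2))
        scale = np.empty((n_ind, n_mark))
        alpha[:, 0] = 0.5 * em[:, 0]
        scale[:, 0] = alpha[:, 0].sum(axis=1)
        alpha[:, 0] /= scale[:, 0, None]
        for j in range(1, n_mark):
            rj = r[j - 1]
            stay, move = 1.0 - rj, rj
            a = alpha[:, j - 1]
            pred = np.stack([a[:, 0] * stay + a[:, 1] * move, a[:, 0] * move + a[:, 1] * stay], axis=1)
            alpha[:, j] = pred * em[:, j]
            scale[:, j] = alpha[:, j].sum(axis=1)
            alpha[:, j] /= scale[:, j, None]
        beta = np.empty((n_ind, n_mark, 2))
        beta[:, -1] = 1.0
        xi = np.empty((n_ind, n_mark - 1)) if n_mark > 1 else np.empty((n_ind, 0))
        for j in range(n_mark - 2, -1, -1):
            rj = r[j]
            stay, move = 1.0 - rj, rj
            b_em = beta[:, j + 1] * em[:, j + 1]
            beta[:, j, 0] = (stay * b_em[:, 0] + move * b_em[:, 1]) / scale[:, j + 1]
            beta[:, j, 1] = (move * b_em[:, 0] + stay * b_em[:, 1]) / scale[:, j + 1]
            # expected transition probability across interval j
            num_move = move * (alpha[:, j, 0] * b_em[:, 1] + alpha[:, j, 1] * b_em[:, 0])
            num_stay = stay * (alpha[:, j, 0] * b_em[:, 0] + alpha[:, j, 1] * b_em[:, 1])
            xi[:, j] = num_move / (num_move + num_stay)
        ll = float(np.log10(scale).sum())
        if n_mark > 1:
            r = np.clip(xi.mean(axis=0), 1e-8, 0.4999)
        if abs(ll - ll_old) < tol:
            break
        ll_old = ll
    return r, ll


def _interval_estimates(matrix: pd.DataFrame, cross_type: str, error_prob: float) -> pd.DataFrame:
    """Adjacent-marker observed discordance, used to seed the EM fit."""
    rows = []
    cols = list(matrix.columns)
    arr = matrix.to_numpy()
    for j in range(len(cols) - 1):
        c0, c1 = cols[j], cols[j + 1]
        if c0[0] != c1[0]:
            continue
        n, disc = _pairwise_discordance(arr[:, j], arr[:, j + 1])
        p_obs = disc / n if n else np.nan
        rows.append({"chrom": c0[0], "pos0": c0[1], "pos1": c1[1], "n_pairs": n, "p_obs": p_obs})
    return pd.DataFrame(rows)


def _encode_genotypes(matrix: pd.DataFrame) -> np.ndarray:
    arr = matrix.to_numpy()
    obs = np.full(arr.shape, -1, dtype=np.int8)
    obs[arr == A] = 0
    obs[arr == B] = 1
    return obs


def _fit_chromosome(matrix: pd.DataFrame, cross_type: str, error_prob: float) -> tuple[np.ndarray, float]:
    """Fitted meiotic recombination fractions + log10-likelihood, one chromosome."""
    obs = _encode_genotypes(matrix)
    iv = _interval_estimates(matrix, cross_type, error_prob)
    init = np.nan_to_num(iv["p_obs"].to_numpy(float), nan=0.01)
    trans, ll = _hmm_em_fractions(obs, init, error_prob)
    trans = np.where(trans < 1e-7, 0.0, trans)  # EM floor -> exact zero
    r = riself_r(trans) if cross_type == "riself" else np.clip(trans, 0.0, 0.4999)
    return r, ll


def _chromosome_log10_likelihood(matrix: pd.DataFrame, cross_type: str, error_prob: float) -> float:
    """Multipoint log10-likelihood of one chromosome's marker data."""
    return _fit_chromosome(matrix, cross_type, error_prob)[1]


class GeneticMap:
    """Ordered markers with physical (bp) and genetic (cM) coordinates."""

    def __init__(self, table: pd.DataFrame, map_function: str = "haldane", error_prob: float = 0.001):
        # table columns: chrom, pos, cm, r_to_next, n_pairs
        self.table = table.reset_index(drop=True)
        self.map_function = map_function
        self.error_prob = error_prob

    def chromosomes(self) -> list[str]:
        return list(dict.fromkeys(self.table["chrom"]))

    def total_cm(self, chrom: str | None = None) -> float:
        if chrom is None:
            return float(sum(self.total_cm(c) for c in self.chromosomes()))
        d = self.table.loc[self.table["chrom"] == chrom, "cm"]
        return float(d.max() - d.min()) if len(d) else 0.0

    def cm_at(self, chrom: str, bp) -> np.ndarray:
        d = self.table.loc[self.table["chrom"] == chrom]
        return np.interp(np.asarray(bp, dtype=float), d["pos"].to_numpy(float), d["cm"].to_numpy(float))

    def bp_at(self, chrom: str, cm) -> np.ndarray:
        d = self.table.loc[self.table["chrom"] == chrom]
        return np.interp(np.asarray(cm, dtype=float), d["cm"].to_numpy(float), d["pos"].to_numpy(float))


def estimate_map(
    matrix: pd.DataFrame,
    cross_type: str = "bc",
    error_prob: float = 0.001,
    map_function: str = "haldane",
) -> GeneticMap:
    """Multipoint ML genetic map on a fixed marker order.

    Per-interval recombination fractions are fitted chromosome by
    chromosome with a 2-state hidden-genotype chain (forward-backward
    EM) whose emission error is ``error_prob``; isolated single-marker
    flips are thereby attributed to genotyping error rather than double
    crossovers, and intervals with missing data are handled by the chain
    itself.  Selfed-line (riself) data are fitted on the fixation-
    discordance scale and converted with r = R / (2(1 - R)).
    """
    if cross_type not in ("bc", "riself"):
        raise ValueError("cross_type must be 'bc' or 'riself'")
    mapf = _MAP_FUNCTIONS[map_function]
    cols = list(matrix.columns)
    rows = []
    for chrom in dict.fromkeys(c[0] for c in cols):
        sub_cols = [c for c in cols if c[0] == chrom]
        sub = matrix[sub_cols]
        iv = _interval_estimates(sub, cross_type, error_prob)
        r, _ = _fit_chromosome(sub, cross_type, error_prob)
        d_cm = np.asarray(mapf(r), dtype=float) if len(r) else np.array([])
        cum = np.concatenate([[0.0], np.cumsum(d_cm)])
        for k, col in enumerate(sub_cols):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": col[1],
                    "cm": cum[k],
                    "r_to_next": r[k] if k < len(r) else np.nan,
                    "n_pairs": iv.loc[k, "n_pairs"] if k < len(iv) else 0,
                }
            )
    return GeneticMap(pd.DataFrame(rows), map_function, error_prob)


# ---------------------------------------------------------------------------
# Marey profiles and low-recombination regions


@dataclass
class RateProfile:
    """Inter-marker recombination rates with a LOESS fit and 95% band."""

    table: pd.DataFrame  # chrom, mid, rate, smoothed, se, lo95, hi95
    genome_average: float
    span: float
    fits: dict[str, LoessFit]

    def predict(self, chrom: str, bp) -> np.ndarray:
        return self.fits[chrom].predict(bp)


def marey_rate_profile(gmap: GeneticMap, span: float = 0.2) -> RateProfile:
    """Local recombination rates (cM/Mb) from a Marey map, LOESS-smoothed.

    Markers at identical physical positions are merged before division.
    The genome-average rate is total cM over total Mb spanned by markers.
    """
    rows = []
    fits: dict[str, LoessFit] = {}
    total_cm = 0.0
    total_mb = 0.0
    for chrom in gmap.chromosomes():
        d = gmap.table.loc[gmap.table["chrom"] == chrom].sort_values("pos")
        d = d.groupby("pos", as_index=False).agg(cm=("cm", "mean"))
        if len(d) < 3:
            warnings.warn(f"{chrom}: fewer than 3 distinct marker positions; skipped in rate profile")
            continue
        pos = d["pos"].to_numpy(float)
        cm = d["cm"].to_numpy(float)
        dmb = np.diff(pos) / 1e6
        rate = np.diff(cm) / dmb
        mid = (pos[:-1] + pos[1:]) / 2.0
        fit = loess_fit(mid, rate, span)
        sm, se = fit.predict_with_se(mid)
        sm = np.maximum(sm, 0.0)
        fits[chrom] = fit
        total_cm += cm[-1] - cm[0]
        total_mb += (pos[-1] - pos[0]) / 1e6
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "mid": mid,
                    "rate": rate,
                    "smoothed": sm,
                    "se": se,
                    "lo95": np.maximum(sm - 1.96 * se, 0.0),
                    "hi95": sm + 1.96 * se,
                }
            )
        )
    if not rows:
        raise ValueError("no chromosome had enough markers for a rate profile")
    table = pd.concat(rows, ignore_index=True)
    return RateProfile(table, genome_average=total_cm / total_mb, span=span, fits=fits)


def low_recombination_regions(
    profile: RateProfile,
    gmap: GeneticMap,
    genes: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Maximal regions where the smoothed rate is strictly below average.

    Regions are unions of consecutive inter-marker intervals whose
    smoothed midpoint rate is below the genome-average rate; bounds snap
    to the flanking marker positions.  Genetic length comes from the
    Marey fit; ``genes`` (columns chrom, pos) adds per-region gene counts
    and the fraction of all genes contained.
    """
    rows = []
    for chrom in profile.fits:
        d = profile.table.loc[profile.table["chrom"] == chrom].reset_index(drop=True)
        markers = gmap.table.loc[gmap.table["chrom"] == chrom, "pos"].sort_values().to_numpy(float)
        # strict inequality with float-equality guard: a profile exactly at
        # the average is not "low recombination"
        cutoff = profile.genome_average - max(1e-12, 1e-9 * abs(profile.genome_average))
        below = (d["smoothed"] < cutoff).to_numpy()
        j = 0
        while j < len(d):
            if not below[j]:
                j += 1
                continue
            j0 = j
            while j < len(d) and below[j]:
                j += 1
            start = float(markers[j0])
            end = float(markers[min(j, len(markers) - 1)])
            cm_len = float(gmap.cm_at(chrom, end) - gmap.cm_at(chrom, start))
            rows.append({"chrom": chrom, "start": start, "end": end, "cm": cm_len})
    regions = pd.DataFrame(rows, columns=["chrom", "start", "end", "cm"])
    if genes is not None and len(regions):
        counts = []
        for _, r in regions.iterrows():
            g = genes.loc[genes["chrom"] == r["chrom"], "pos"]
            counts.append(int(((g >= r["start"]) & (g <= r["end"])).sum()))
        regions["n_genes"] = counts
        regions["gene_fraction"] = regions["n_genes"] / max(len(genes), 1)
    return regions


def _domain_segments(
    gmap: GeneticMap,
    chrom_lengths: dict[str, float],
    exclude: pd.DataFrame | None,
) -> pd.DataFrame:
    """Genomic segments available for bootstrap sampling, with cM bounds."""
    segs = []
    for chrom, L in chrom_lengths.items():
        cuts = [(1.0, float(L))]
        if exclude is not None:
            for _, r in exclude.loc[exclude["chrom"] == chrom].iterrows():
                new = []
                for s, e in cuts:
                    if r["end"] < s or r["start"] > e:
                        new.append((s, e))
                        continue
                    if s < r["start"]:
                        new.append((s, r["start"]))
                    if r["end"] < e:
                        new.append((r["end"], e))
                cuts = new
        for s, e in cuts:
            if e > s:
                segs.append({"chrom": chrom, "start": s, "end": e})
    return pd.DataFrame(segs)


def bootstrap_gene_fraction_test(
    regions: pd.DataFrame,
    gmap: GeneticMap,
    genes: pd.DataFrame,
    chrom_lengths: dict[str, float] | None = None,
    n_iter: int = 10_000,
    seed: int = 0,
    domain: str = "outside",
) -> tuple[float, np.ndarray, float]:
    """Bootstrap test: are the regions gene-enriched for their genetic length?

    Per iteration one genomic region with the observed regions' total
    genetic distance is drawn (from the genome excluding the observed
    regions by default, or ``domain='genome'`` for the whole genome) and
    its gene fraction recorded.  Returns (one-tailed p, null fractions,
    observed fraction) with p = (1 + #{null >= observed}) / (n_iter + 1).
    """
    if genes is None or len(genes) == 0:
        raise ValueError("no genes supplied")
    if chrom_lengths is None:
        chrom_lengths = {
            c: float(gmap.table.loc[gmap.table["chrom"] == c, "pos"].max()) for c in gmap.chromosomes()
        }
    target_cm = float(regions["cm"].sum())
    exclude = regions if domain == "outside" else None
    segs = _domain_segments(gmap, chrom_lengths, exclude)
    if segs.empty:
        raise ValueError("empty sampling domain")
    # flatten everything to numpy for the sampling loop
    marker_pos = {c: gmap.table.loc[gmap.table["chrom"] == c, "pos"].to_numpy(float) for c in gmap.chromosomes()}
    marker_cm = {c: gmap.table.loc[gmap.table["chrom"] == c, "cm"].to_numpy(float) for c in gmap.chromosomes()}
    seg_chrom = segs["chrom"].to_list()
    seg_start = segs["start"].to_numpy(float)
    seg_end = segs["end"].to_numpy(float)
    seg_cm_end = np.array(
        [np.interp(e, marker_pos[c], marker_cm[c]) for c, e in zip(seg_chrom, seg_end)]
    )
    cum = np.concatenate([[0.0], np.cumsum(seg_end - seg_start)])
    gene_pos = {c: np.sort(genes.loc[genes["chrom"] == c, "pos"].to_numpy(float)) for c in genes["chrom"].unique()}
    n_genes = len(genes)
    empty = np.array([], dtype=float)

    def count_genes(chrom: str, lo: float, hi: float) -> int:
        g = gene_pos.get(chrom, empty)
        return int(np.searchsorted(g, hi, side="right") - np.searchsorted(g, lo, side="left"))

    observed = sum(count_genes(r["chrom"], r["start"], r["end"]) for _, r in regions.iterrows()) / n_genes

    rng = np.random.default_rng(np.random.SeedSequence((seed, 505)))
    null = np.empty(n_iter)
    available_cm = float(
        np.sum(seg_cm_end - [np.interp(s, marker_pos[c], marker_cm[c]) for c, s in zip(seg_chrom, seg_start)])
    )
    if target_cm > available_cm + 1e-9:
        raise ValueError("sampling domain too short for the required genetic distance")
    for it in range(n_iter):
        remaining = target_cm
        hits = 0
        guard = 0
        while remaining > 1e-9:
            guard += 1
            if guard > 1000:
                raise RuntimeError("bootstrap region placement did not converge")
            u = rng.uniform(0.0, cum[-1])
            si = min(int(np.searchsorted(cum, u, side="right")) - 1, len(seg_chrom) - 1)
            chrom = seg_chrom[si]
            start_bp = seg_start[si] + (u - cum[si])
            cm_start = float(np.interp(start_bp, marker_pos[chrom], marker_cm[chrom]))
            gained = min(remaining, seg_cm_end[si] - cm_start)
            if gained <= 0:
                # flat stretch to the segment end: wrap to a new start
                continue
            end_bp = float(np.interp(cm_start + gained, marker_cm[chrom], marker_pos[chrom]))
            end_bp = min(end_bp, seg_end[si])
            hits += count_genes(chrom, start_bp, end_bp)
            remaining -= gained
        null[it] = hits / n_genes
    p = (1.0 + float((null >= observed - 1e-12).sum())) / (n_iter + 1.0)
    return p, null, observed


# ---------------------------------------------------------------------------
# recombination sites and the fertility GLM


def detect_recombination_sites(
    calls: pd.DataFrame,
    fusion_chrom: str | None = None,
    breakpoint_bp: float = 21_050_000.0,
    exclusion_half_width: float = 1_000_000.0,
    trisomic_ids: tuple[str, ...] = (),
    missing: tuple[str, ...] = (U, "missing"),
) -> tuple[pd.DataFrame, list[str]]:
    """Genotype-change points per individual, with trisomy exclusions.

    ``calls`` is individuals x (chrom, start) categorical genotypes.  A
    site is recorded at the midpoint between adjacent non-missing
    windows of differing genotype.  Individuals called trisomic upstream
    are dropped first; individuals with a genotype change inside
    ``breakpoint_bp +/- exclusion_half_width`` on ``fusion_chrom`` are
    dropped as possible undetected trisomics.
    """
    sites = []
    excluded = [i for i in calls.index if i in set(trisomic_ids)]
    chroms = calls.columns.get_level_values(0)
    for ind in calls.index:
        if ind in set(trisomic_ids):
            continue
        ind_sites = []
        bad = False
        for chrom in dict.fromkeys(chroms):
            row = calls.loc[ind, chrom]
            starts = row.index.to_numpy(float)
            vals = row.to_numpy()
            keep = ~np.isin(vals, missing)
            starts, vals = starts[keep], vals[keep]
            for j in range(len(vals) - 1):
                if vals[j] != vals[j + 1]:
                    mid = (starts[j] + starts[j + 1]) / 2.0
                    if (
                        fusion_chrom is not None
                        and chrom == fusion_chrom
                        and abs(mid - breakpoint_bp) <= exclusion_half_width
                    ):
                        bad = True
                    ind_sites.append({"individual": ind, "chrom": chrom, "midpoint": mid,
                                      "left": vals[j], "right": vals[j + 1]})
        if bad:
            excluded.append(ind)
        else:
            sites.extend(ind_sites)
    return pd.DataFrame(sites, columns=["individual", "chrom", "midpoint", "left", "right"]), excluded


@dataclass
class GlmResult:
    coefficient: float | None
    lrt: float | None
    p: float | None
    n: int
    separated: bool


def recombination_fertility_glm(
    sites: pd.DataFrame,
    has_progeny: pd.Series,
    region: tuple[str, float, float],
) -> GlmResult:
    """Logistic fertility ~ recombination-site position, tested by LRT.

    Individuals are restricted to those with at least one recombination
    site inside ``region`` (chrom, start, end); the covariate is the
    mean site midpoint in Mb.  The likelihood-ratio statistic against
    the intercept-only model is referred to chi-squared with 1 df.
    Complete separation is flagged and no p-value reported.
    """
    import statsmodels.api as sm

    chrom, lo, hi = region
    d = sites.loc[(sites["chrom"] == chrom) & (sites["midpoint"] >= lo) & (sites["midpoint"] <= hi)]
    if d.empty:
        raise ValueError("no recombination sites in the region")
    pos = d.groupby("individual")["midpoint"].mean() / 1e6
    common = pos.index.intersection(has_progeny.index)
    pos = pos.loc[common]
    y = has_progeny.loc[common].astype(float)
    n = len(pos)
    if n < 3 or y.nunique() < 2:
        return GlmResult(None, None, None, n, separated=True)
    x = sm.add_constant(pos.to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            full = sm.GLM(y.to_numpy(), x, family=sm.families.Binomial()).fit(maxiter=200)
            null_ = sm.GLM(y.to_numpy(), np.ones((n, 1)), family=sm.families.Binomial()).fit()
        except Exception:
            return GlmResult(None, None, None, n, separated=True)
    coef = float(full.params[1])
    mu = full.fittedvalues
    separated = bool(np.all((mu < 1e-8) | (mu > 1 - 1e-8))) or abs(coef) > 50
    if separated:
        return GlmResult(coef, None, None, n, separated=True)
    lrt = float(2.0 * (full.llf - null_.llf))
    p = float(stats.chi2.sf(max(lrt, 0.0), df=1))
    return GlmResult(coef, lrt, p, n, separated=False)
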