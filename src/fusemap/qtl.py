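"""Genome-wide sterility QTL scan on window introgression calls.

Each window yields a 2x2 table {introgression present/absent} x {progeny
present/absent} tested with a two-sided Fisher exact test (point-
probability rule: the p-value sums all tables, at fixed margins, whose
hypergeometric probability does not exceed the observed one).  Genome-
wide significance comes from a permutation test that shuffles the
phenotype vector across individuals and records the genome-wide minimum
p per permutation; the threshold is the empirical alpha-quantile of
those minima.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

PRESENT = "present"
ABSENT = "absent"
MISSING = "missing"

# relative slack when comparing point probabilities, as in R's fisher.test
_REL_EPS = 1e-7


@lru_cache(maxsize=100_000)
def _two_sided_p_vector(n: int, m: int, a: int) -> np.ndarray:
    """Two-sided Fisher p for every feasible cell count k.

    Margins: n individuals, m with progeny, a with the introgression;
    k = count with both.  Entry j of the returned vector is the p-value
    for k = k_min + j.
    """
    k_min = max(0, a + m - n)
    k_max = min(a, m)
    ks = np.arange(k_min, k_max + 1)
    pmf = stats.hypergeom.pmf(ks, n, m, a)
    p = np.array([pmf[pmf <= pmf[j] * (1 + _REL_EPS)].sum() for j in range(ks.size)])
    p = np.minimum(p, 1.0)
    # the full support sums to 1 only up to float error
    p[p > 1.0 - 1e-9] = 1.0
    return p


def fisher_two_sided(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table [[a, b], [c, d]]."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("table must be 2x2 with non-negative counts")
    n = int(t.sum())
    m = int(t[:, 0].sum())
    a = int(t[0, :].sum())
    if n == 0 or m in (0, n) or a in (0, n):
        return 1.0
    vec = _two_sided_p_vector(n, m, a)
    k_min = max(0, a + m - n)
    return float(vec[int(t[0, 0]) - k_min])


@dataclass
class ScanResult:
    """Per-window Fisher scan with permutation threshold and QTL calls."""

    windows: pd.DataFrame  # chrom, start, n, a (introgressed), k (introgressed & progeny), p, degenerate
    threshold: float | None = None
    perm_minima: np.ndarray | None = None
    qtl_intervals: pd.DataFrame = field(default_factory=pd.DataFrame)


def qc_filter_panel(
    phenotypes: pd.DataFrame,
    calls: pd.DataFrame,
    mode: str = "female",
    selfing_progeny_threshold: int = 20,
    selfing_normal_fraction: float = 0.8,
    drop_chrx: bool | None = None,
    x_chroms: tuple[str, ...] = ("ChrX", "X"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the study's panel quality-control rules.

    ``phenotypes`` is indexed by individual with at least ``n_progeny``;
    hermaphrodite mode additionally uses ``normal_fraction`` and
    ``has_male_siblings`` to drop putative self-progeny (more than
    ``selfing_progeny_threshold`` progeny of which more than
    ``selfing_normal_fraction`` develop normally) and individuals
    lacking male siblings.  ChrX windows are dropped from the tested set
    when the design gives the X no F1-male variation (default: in male
    and hermaphrodite modes, where BC1 derive from F1 males).
    """
    phen = phenotypes.copy()
    if mode == "hermaphrodite":
        selfed = (phen["n_progeny"] > selfing_progeny_threshold) & (
            phen.get("normal_fraction", pd.Series(0.0, index=phen.index)) > selfing_normal_fraction
        )
        phen = phen.loc[~selfed]
        if "has_male_siblings" in phen.columns:
            phen = phen.loc[phen["has_male_siblings"].astype(bool)]
    if drop_chrx is None:
        drop_chrx = mode in ("male", "hermaphrodite")
    kept_calls = calls.loc[calls.index.intersection(phen.index)]
    if drop_chrx:
        chroms = kept_calls.columns.get_level_values(0)
        kept_calls = kept_calls.loc[:, ~chroms.isin(x_chroms)]
    phen = phen.loc[kept_calls.index]
    if phen.empty:
        raise ValueError("panel empty after quality-control filtering")
    return phen, kept_calls


def _encode_calls(calls: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Boolean genotype and validity masks from a string call matrix."""
    arr = calls.to_numpy()
    geno = arr == PRESENT
    valid = geno | (arr == ABSENT)
    return geno, valid


def fisher_window_scan(calls: pd.DataFrame, has_progeny: pd.Series) -> pd.DataFrame:
    """Two-sided Fisher p per window; missing calls excluded pairwise.

    ``calls`` is individuals x windows (values present/absent/missing),
    ``has_progeny`` a boolean Series over the same individuals.
    """
    if len(calls) < 2:
        raise ValueError("need at least 2 individuals")
    pheno = has_progeny.loc[calls.index].to_numpy(dtype=bool)
    geno, valid = _encode_calls(calls)
    n_w = geno.shape[1]
    p = np.ones(n_w)
    degenerate = np.zeros(n_w, dtype=bool)
    rows = []
    for j in range(n_w):
        v = valid[:, j]
        g = geno[v, j]
        ph = pheno[v]
        n, m, a, k = int(v.sum()), int(ph.sum()), int(g.sum()), int((g & ph).sum())
        if n == 0 or a in (0, n) or m in (0, n):
            degenerate[j] = True
        else:
            vec = _two_sided_p_vector(n, m, a)
            p[j] = vec[k - max(0, a + m - n)]
        rows.append((n, m, a, k))
    out = pd.DataFrame(rows, columns=["n", "m", "a", "k"])
    if isinstance(calls.columns, pd.MultiIndex):
        out.insert(0, "chrom", calls.columns.get_level_values(0))
        out.insert(1, "start", calls.columns.get_level_values(1))
    else:
        out.insert(0, "window", calls.columns)
    out["p"] = p
    out["neg_log10_p"] = -np.log10(p)
    out["degenerate"] = degenerate
    return out


def permutation_threshold(
    calls: pd.DataFrame,
    has_progeny: pd.Series,
    n_perm: int = 1000,
    alpha: float = 0.01,
    seed: int = 0,
) -> tuple[float, np.ndarray]:
    """Genome-wide p threshold from phenotype-permutation minima.

    The phenotype vector is randomly reassigned across individuals
    ``n_perm`` times; per permutation the genome-wide minimum Fisher p
    is recorded and the threshold is the ``alpha``-quantile (k-th order
    statistic, k = floor(alpha * n_perm)) of these minima.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    pheno = has_progeny.loc[calls.index].to_numpy(dtype=bool)
    if pheno.all() or (~pheno).all():
        raise ValueError("degenerate phenotype vector: permutation threshold undefined")
    rng = np.random.default_rng(np.random.SeedSequence((seed, 404)))
    geno, valid = _encode_calls(calls)
    n_ind, n_w = geno.shape
    perms = np.empty((n_ind, n_perm), dtype=np.float64)
    for t in range(n_perm):
        perms[:, t] = pheno[rng.permutation(n_ind)]
    gv = (geno & valid).astype(np.float64)
    v = valid.astype(np.float64)
    ks = gv.T @ perms  # windows x perms: introgressed & progeny among valid
    ms = v.T @ perms  # windows x perms: progeny among valid
    ns = valid.sum(axis=0)  # per-window n
    as_ = (geno & valid).sum(axis=0)  # per-window a
    minima = np.ones(n_perm)
    for j in range(n_w):
        n, a = int(ns[j]), int(as_[j])
        if n == 0 or a in (0, n):
            continue
        m_row = ms[j].astype(int)
        k_row = ks[j].astype(int)
        pj = np.ones(n_perm)
        for m in np.unique(m_row):
            if m in (0, n):
                continue
            vec = _two_sided_p_vector(n, int(m), a)
            sel = m_row == m
            pj[sel] = vec[k_row[sel] - max(0, a + int(m) - n)]
        minima = np.minimum(minima, pj)
    k_order = max(1, int(np.floor(alpha * n_perm)))
    threshold = float(np.sort(minima)[k_order - 1])
    return threshold, minima


def call_qtl_regions(scan: pd.DataFrame, threshold: float, gap_tolerance: int = 0) -> pd.DataFrame:
    """Merge runs of significant windows (p strictly below threshold).

    Runs separated by more than ``gap_tolerance`` non-significant
    windows become separate intervals; each interval reports its
    minimum-p window as the peak.
    """
    out = []
    for chrom, d in scan.groupby("chrom", sort=False):
        d = d.sort_values("start").reset_index(drop=True)
        step = int(d["start"].diff().mode().iloc[0]) if len(d) > 1 else 1
        sig = (d["p"] < threshold).to_numpy()
        i = 0
        while i < len(d):
            if not sig[i]:
                i += 1
                continue
            j = i
            gap = 0
            end = i
            while j + 1 < len(d):
                if sig[j + 1]:
                    gap = 0
                    end = j + 1
                else:
                    gap += 1
                    if gap > gap_tolerance:
                        break
                j += 1
            block = d.iloc[i : end + 1]
            peak = block.loc[block["p"].idxmin()]
            out.append(
                {
                    "chrom": chrom,
                    "start": int(block["start"].min()),
                    "end": int(block["start"].max() + step - 1),
                    "peak_start": int(peak["start"]),
                    "peak_p": float(peak["p"]),
                    "n_windows": int(sig[i : end + 1].sum()),
                }
            )
            i = end + 1
    return pd.DataFrame(out, columns=["chrom", "start", "end", "peak_start", "peak_p", "n_windows"])
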