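"""Backcross / F3 / RIL panel simulation with map-driven meiosis.

Individuals carry per-element ancestry-segment haplotypes (1-based
inclusive intervals labelled with a species/strain of origin).  Meiosis
places crossovers according to a Marey map: by default each element is a
recombination unit with at most one crossover per gamete (holocentric
nematode bivalents typically show a single chiasma), with a Poisson
alternative.  F1 nondisjunction of the fused element IR produces trisomic
backcross progeny.  Low-coverage sequencing is emulated as Poisson read
counts per diagnostic site with symmetric allele error.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .karyotype import GeneticMapModel

# one ancestry segment: (start, end, origin), 1-based inclusive
Segment = tuple[int, int, str]
Copy = list[Segment]


@dataclass
class CoverageModel:
    """Sequencing-depth model for single-worm low-coverage data."""

    mean_depth_per_site: float = 0.2
    error_rate: float = 0.005
    base_quality_min: int = 13

    def __post_init__(self):
        if self.mean_depth_per_site <= 0:
            raise ValueError("mean_depth_per_site must be > 0")
        if not (0.0 <= self.error_rate < 0.5):
            raise ValueError("error_rate must be in [0, 0.5)")


@dataclass
class PhenotypeModel:
    """Logistic sterility model with QTL, trisomy and recombination terms.

    fertility probability = logistic(beta0 + beta_qtl * I + beta_tri * T
    + beta_rec * D) where I indicates introgression at the QTL position,
    T indicates IR trisomy and D is the displacement (Mb) of the
    individual's crossover sites toward the centre of ``rec_element``.
    """

    beta0: float = 1.5
    beta_qtl: float = -3.0
    beta_tri: float = -3.0
    beta_rec: float = 0.0
    qtl_element: str = "IR"
    qtl_pos: int = 6_000_000
    rec_element: str = "IR"
    progeny_mean: float = 30.0
    progeny_dispersion: float = 2.0


@dataclass
class SimulatedIndividual:
    id: str
    role: str
    # element -> list of chromosome copies, each a segment list
    haplotypes: dict[str, list[Copy]]
    copy_number: dict[str, int] = field(default_factory=dict)
    fertile: bool | None = None
    n_progeny: int | None = None

    def __post_init__(self):
        if not self.copy_number:
            self.copy_number = {el: len(c) for el, c in self.haplotypes.items()}
        for el, copies in self.haplotypes.items():
            if len(copies) not in (1, 2, 3):
                raise ValueError(f"{self.id}: element {el} has {len(copies)} copies")


def origins_at(copy: Copy, positions: np.ndarray) -> np.ndarray:
    """Origin label of a chromosome copy at each queried position."""
    starts = np.array([s for s, _, _ in copy])
    labels = np.array([o for _, _, o in copy])
    idx = np.searchsorted(starts, positions, side="right") - 1
    if np.any(idx < 0) or np.any(positions > copy[-1][1]):
        raise ValueError("position outside the copy's extent")
    return labels[idx]


def ancestry_dose(ind: SimulatedIndividual, element: str, positions: np.ndarray, origin: str) -> np.ndarray:
    """Number of copies of ``element`` carrying ``origin`` at each position."""
    dose = np.zeros(len(positions), dtype=int)
    for copy in ind.haplotypes[element]:
        dose += origins_at(copy, positions) == origin
    return dose


def _pure(length: int, origin: str) -> Copy:
    return [(1, length, origin)]


def _mosaic(length: int, breakpoints: list[float], first: str, second: str) -> Copy:
    """Segments alternating between two origins at the given breakpoints."""
    bps = sorted(int(round(b)) for b in breakpoints)
    bps = [b for b in bps if 1 <= b < length]
    segs: Copy = []
    cur, origin = 1, first
    for b in bps:
        if b >= cur:
            segs.append((cur, b, origin))
            cur = b + 1
        origin = second if origin == first else first
    segs.append((cur, length, origin))
    # merge adjacent same-origin runs (possible with coincident breakpoints)
    merged: Copy = [segs[0]]
    for s, e, o in segs[1:]:
        ps, pe, po = merged[-1]
        if o == po:
            merged[-1] = (ps, e, po)
        else:
            merged.append((s, e, o))
    return merged


def gamete(
    lengths: dict[str, int],
    map_model: GeneticMapModel,
    origins: tuple[str, str],
    rng: np.random.Generator,
    crossover_mode: str = "obligate",
    units: list[tuple[str, ...]] | None = None,
) -> dict[str, Copy]:
    """One recombinant gamete from a parent with two pure-origin homologs.

    ``units`` groups elements into recombination units (default: each
    element on its own); crossover counts are drawn per unit from its
    total genetic length.
    """
    if units is None:
        units = [(e,) for e in lengths]
    out: dict[str, Copy] = {}
    for unit in units:
        total_cm = map_model.chromosome_total_cm(unit)
        if crossover_mode == "obligate":
            p_co = total_cm / 100.0
            if p_co > 1.0:
                warnings.warn(f"unit {unit}: map {total_cm} cM exceeds 100 cM; obligate mode caps at one crossover")
                p_co = 1.0
            n_co = int(rng.random() < p_co)
        elif crossover_mode == "poisson":
            n_co = int(rng.poisson(total_cm / 100.0))
        else:
            raise ValueError(f"unknown crossover_mode {crossover_mode!r}")
        # crossover positions via inverse Marey, on unit-concatenated coordinates
        offsets: dict[str, int] = {}
        off = 0
        for el in unit:
            offsets[el] = off
            off += lengths[el]
        total_len = off
        bps = []
        for _ in range(n_co):
            el, pos = map_model.sample_crossover(unit, rng)
            bps.append(offsets[el] + pos)
        first = origins[rng.integers(0, 2)]
        other = origins[1] if first == origins[0] else origins[0]
        concat = _mosaic(total_len, bps, first, other)
        # slice the unit mosaic back into per-element copies
        for el in unit:
            lo, hi = offsets[el] + 1, offsets[el] + lengths[el]
            copy: Copy = []
            for s, e, o in concat:
                s2, e2 = max(s, lo), min(e, hi)
                if s2 <= e2:
                    copy.append((s2 - offsets[el], e2 - offsets[el], o))
            out[el] = copy
    return out


def _ril_copy(length: int, map_model: GeneticMapModel, element: str, rng: np.random.Generator, grid_bp: int, origins=("A", "B")) -> Copy:
    """A fixed recombinant-inbred haplotype via the Haldane–Waddington chain.

    Adjacent grid points switch genotype with probability R = 2r/(1+2r),
    the expected fixation-discordance for selfed lines.
    """
    grid = np.arange(1, length + 1, grid_bp)
    if grid[-1] != length:
        grid = np.append(grid, length)
    cm = map_model.cm_at(element, grid)
    r = np.clip(np.diff(cm) / 100.0, 0.0, 0.5)
    big_r = 2 * r / (1 + 2 * r)
    flips = rng.random(big_r.size) < big_r
    state = rng.integers(0, 2)
    states = (state + np.concatenate([[0], np.cumsum(flips)])) % 2
    bps = [float(grid[i + 1] - 1) for i in range(flips.size) if flips[i]]
    return _mosaic(length, bps, origins[states[0]], origins[1 - states[0]])


def simulate_cross_panel(
    design: str,
    n: int,
    map_model: GeneticMapModel,
    lengths: dict[str, int] | None = None,
    nondisjunction_rate: float = 0.0,
    seed: int = 0,
    crossover_mode: str = "obligate",
    units: list[tuple[str, ...]] | None = None,
    ril_grid_bp: int = 100_000,
) -> list[SimulatedIndividual]:
    """Simulate a panel of hybrids under one of the study's cross designs.

    Designs
    -------
    ``bc1_to_P``  F1 (P x E) gamete + pure species-P homolog; introgression
                  is E-derived material.
    ``bc1_to_E``  F1 gamete + pure species-E homolog; introgression is
                  P-derived.
    ``f3``        grand-progeny of two mutant founders: one recombinant
                  A/B haplotype (the genotyped F2 meiosis) plus a wild-type
                  homolog carrying no founder-unique markers.
    ``ril``       recombinant inbred lines fixed for A/B mosaics.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= nondisjunction_rate <= 1.0):
        raise ValueError("nondisjunction_rate must be in [0, 1]")
    if lengths is None:
        lengths = {e: map_model._knots[e][0][-1].astype(int) for e in map_model.elements()}
        lengths = {e: int(v) for e, v in lengths.items()}
    design_tag = {"bc1_to_P": 1, "bc1_to_E": 2, "f3": 3, "ril": 4}.get(design, 0)
    ss = np.random.SeedSequence((seed, design_tag))
    rngs = [np.random.default_rng(s) for s in ss.spawn(n)]

    panel: list[SimulatedIndividual] = []
    for i, rng in enumerate(rngs):
        if design in ("bc1_to_P", "bc1_to_E"):
            g = gamete(lengths, map_model, ("P", "E"), rng, crossover_mode, units)
            parental = "P" if design == "bc1_to_P" else "E"
            hap = {el: [_pure(lengths[el], parental), g[el]] for el in lengths}
            if rng.random() < nondisjunction_rate:
                # F1 IR bivalent fails to disjoin: the gamete carries both homologs
                hap["IR"] = [_pure(lengths["IR"], parental), _pure(lengths["IR"], "P"), _pure(lengths["IR"], "E")]
            role = "BC1"
        elif design == "f3":
            g = gamete(lengths, map_model, ("A", "B"), rng, crossover_mode, units)
            hap = {el: [g[el], _pure(lengths[el], "WT")] for el in lengths}
            role = "F3"
        elif design == "ril":
            copies = {el: _ril_copy(lengths[el], map_model, el, rng, ril_grid_bp) for el in lengths}
            hap = {el: [copies[el], [tuple(s) for s in copies[el]]] for el in lengths}
            role = "RIL"
        else:
            raise ValueError(f"unknown cross design {design!r}")
        panel.append(SimulatedIndividual(id=f"{design}_{i:04d}", role=role, haplotypes=hap))
    return panel


def simulate_allele_depths(
    panel: list[SimulatedIndividual],
    site_positions: dict[str, np.ndarray],
    coverage: CoverageModel,
    seed: int = 0,
    alt_origin: str = "E",
) -> dict[str, pd.DataFrame]:
    """Poisson low-coverage allele depths at diagnostic sites.

    Per site the read count is Poisson(mean depth x copies/2); each read
    reports the allele of a uniformly chosen chromosome copy (the
    ``alt_origin`` species carries the alternative allele) and is flipped
    with probability ``error_rate``.
    """
    if not panel:
        raise ValueError("panel is empty")
    ss = np.random.SeedSequence((seed, 101))
    tables: dict[str, pd.DataFrame] = {}
    for ind, child in zip(panel, ss.spawn(len(panel))):
        rng = np.random.default_rng(child)
        frames = []
        for el, pos in site_positions.items():
            pos = np.asarray(pos, dtype=int)
            ncop = len(ind.haplotypes[el])
            dose = ancestry_dose(ind, el, pos, alt_origin)
            depth = rng.poisson(coverage.mean_depth_per_site * ncop / 2.0, size=pos.size)
            alt_true = rng.binomial(depth, dose / ncop)
            e = coverage.error_rate
            alt_obs = rng.binomial(alt_true, 1.0 - e) + rng.binomial(depth - alt_true, e)
            frames.append(
                pd.DataFrame(
                    {"element": el, "pos": pos, "ref_count": depth - alt_obs, "alt_count": alt_obs}
                )
            )
        tables[ind.id] = pd.concat(frames, ignore_index=True)
    return tables


def simulate_window_coverage(
    panel: list[SimulatedIndividual],
    lengths: dict[str, int],
    window_size: int = 100_000,
    mean_window_depth: float = 20.0,
    lognormal_sigma: float = 0.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-window sequencing depth with multiplicative lognormal noise.

    Depth scales with element copy number (three copies -> 1.5x).
    Returns a long table (individual, element, start, end, depth).
    """
    ss = np.random.SeedSequence((seed, 202))
    rows = []
    for ind, child in zip(panel, ss.spawn(len(panel))):
        rng = np.random.default_rng(child)
        for el, L in lengths.items():
            starts = np.arange(1, L + 1, window_size)
            ends = np.minimum(starts + window_size - 1, L)
            cn = len(ind.haplotypes[el])
            noise = rng.lognormal(0.0, lognormal_sigma, size=starts.size)
            depth = mean_window_depth * (cn / 2.0) * noise
            rows.append(
                pd.DataFrame(
                    {"individual": ind.id, "element": el, "start": starts, "end": ends, "depth": depth}
                )
            )
    return pd.concat(rows, ignore_index=True)


def crossover_breakpoints(ind: SimulatedIndividual, element: str) -> list[int]:
    """Ancestry-breakpoint positions (bp) on the recombinant copies."""
    bps = []
    for copy in ind.haplotypes[element]:
        for (s, e, o), (s2, e2, o2) in zip(copy, copy[1:]):
            if o != o2:
                bps.append(e)
    return sorted(bps)


def assign_phenotypes(
    panel: list[SimulatedIndividual],
    model: PhenotypeModel,
    seed: int = 0,
    introgressed_origin: str = "E",
) -> list[SimulatedIndividual]:
    """Draw fertility flags and progeny counts in place (returns the panel)."""
    ss = np.random.SeedSequence((seed, 303))
    for ind, child in zip(panel, ss.spawn(len(panel))):
        rng = np.random.default_rng(child)
        pos = np.array([model.qtl_pos])
        has_qtl = ancestry_dose(ind, model.qtl_element, pos, introgressed_origin)[0] > 0
        trisomic = len(ind.haplotypes.get("IR", [])) == 3
        bps = crossover_breakpoints(ind, model.rec_element)
        if bps:
            L = ind.haplotypes[model.rec_element][0][-1][1]
            disp = float(np.mean([min(b, L - b) for b in bps])) / 1e6
        else:
            disp = 0.0
        lp = model.beta0 + model.beta_qtl * has_qtl + model.beta_tri * trisomic + model.beta_rec * disp
        p = 1.0 / (1.0 + np.exp(-lp)) if np.isfinite(lp) else (0.0 if lp < 0 else 1.0)
        ind.fertile = bool(rng.random() < p)
        if ind.fertile:
            m, k = model.progeny_mean, model.progeny_dispersion
            ind.n_progeny = 1 + int(rng.negative_binomial(k, k / (k + m)))
        else:
            ind.n_progeny = 0
    return panel


def true_window_calls(
    panel: list[SimulatedIndividual],
    lengths: dict[str, int],
    window_size: int = 100_000,
    origin: str = "E",
    exclude_pure_parent: bool = True,
) -> pd.DataFrame:
    """Ground-truth window introgression matrix from the haplotypes.

    A window is 'present' when any non-parental copy carries ``origin``
    at the window centre.  Windows overlapping an ancestry breakpoint are
    ambiguous by construction; see :func:`breakpoint_windows`.
    """
    cols: dict[str, np.ndarray] = {}
    win_index = []
    for el, L in lengths.items():
        starts = np.arange(1, L + 1, window_size)
        centres = np.minimum(starts + window_size // 2, L)
        win_index += [(el, int(s)) for s in starts]
        cols[el] = centres
    data = {}
    for ind in panel:
        calls = []
        for el in lengths:
            centres = cols[el]
            copies = ind.haplotypes[el]
            if exclude_pure_parent and ind.role == "BC1":
                copies = copies[1:]
            dose = np.zeros(centres.size, dtype=int)
            for copy in copies:
                dose += origins_at(copy, centres) == origin
            calls.append(dose > 0)
        data[ind.id] = np.concatenate(calls)
    idx = pd.MultiIndex.from_tuples(win_index, names=["element", "start"])
    return pd.DataFrame(data, index=idx).T


def breakpoint_windows(
    panel: list[SimulatedIndividual], lengths: dict[str, int], window_size: int = 100_000
) -> dict[str, set[tuple[str, int]]]:
    """Windows containing a true ancestry breakpoint, per individual."""
    out: dict[str, set[tuple[str, int]]] = {}
    for ind in panel:
        hit = set()
        for el in lengths:
            for b in crossover_breakpoints(ind, el):
                start = ((b - 1) // window_size) * window_size + 1
                hit.add((el, int(start)))
        out[ind.id] = hit
    return out
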