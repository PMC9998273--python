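"""Chromosomal elements, karyotypes and Marey-map models.

The system modelled here is a pair of sibling nematode species that share
seven ancestral chromosomal elements (ChrIL, ChrIR, ChrII, ChrIII, ChrIV,
ChrV, ChrX) but package them differently: species "P" fuses IL+IR into one
large chromosome (ChrI, breakpoint at 21.05 Mb), species "E" fuses IR+X
into a large neo-X (ChrX*), and an outgroup karyotype keeps all seven
elements separate.  All public coordinates are 1-based inclusive; only BED
output converts to 0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

ELEMENT_NAMES = ("IL", "IR", "II", "III", "IV", "V", "X")
DEFAULT_BREAKPOINT_BP = 21_050_000

#: element lengths (bp) loosely following the real chromosome sizes:
#: IL+IR make a ~34 Mb fused chromosome split at 21.05 Mb.
DEFAULT_ELEMENT_LENGTHS = {
    "IL": 21_050_000,
    "IR": 13_000_000,
    "II": 20_000_000,
    "III": 20_000_000,
    "IV": 20_000_000,
    "V": 20_000_000,
    "X": 20_000_000,
}


@dataclass(frozen=True)
class ChromosomeElement:
    """One ancestral chromosomal element with its annotated positions."""

    name: str
    length: int
    gene_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    snp_positions: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        if self.name not in ELEMENT_NAMES:
            raise ValueError(f"unknown element name {self.name!r}")
        if self.length <= 0:
            raise ValueError(f"element {self.name}: length must be positive")
        for attr in ("gene_positions", "snp_positions"):
            pos = np.asarray(getattr(self, attr), dtype=int)
            object.__setattr__(self, attr, pos)
            if pos.size:
                if not np.all(np.diff(pos) > 0):
                    raise ValueError(f"element {self.name}: {attr} must be strictly increasing")
                if pos[0] < 1 or pos[-1] > self.length:
                    raise ValueError(f"element {self.name}: {attr} outside [1, length]")


@dataclass(frozen=True)
class KaryotypeConfig:
    """How a species packages the seven elements into chromosomes.

    ``fusions`` lists ordered element pairs joined head-to-tail; every
    element not named in a fusion becomes a chromosome of its own.
    """

    species: str
    fusions: tuple[tuple[str, str], ...] = ()
    breakpoint_bp: int = DEFAULT_BREAKPOINT_BP

    def __post_init__(self):
        seen: set[str] = set()
        for a, b in self.fusions:
            for e in (a, b):
                if e not in ELEMENT_NAMES:
                    raise ValueError(f"unknown element {e!r} in fusion")
                if e in seen:
                    raise ValueError(f"element {e!r} assigned to more than one chromosome")
                seen.add(e)

    def chromosome_composition(self) -> list[tuple[str, ...]]:
        """Ordered element tuples, one per chromosome, in ELEMENT_NAMES order."""
        fused = {e for pair in self.fusions for e in pair}
        chroms: list[tuple[str, ...]] = [tuple(pair) for pair in self.fusions]
        chroms += [(e,) for e in ELEMENT_NAMES if e not in fused]
        first = {c: min(ELEMENT_NAMES.index(e) for e in c) for c in chroms}
        return sorted(chroms, key=lambda c: first[c])


def chromosome_name(elements: tuple[str, ...]) -> str:
    """Conventional chromosome name for an element combination."""
    if elements == ("IL", "IR"):
        return "ChrI"
    if elements == ("IR", "X"):
        return "ChrX*"
    if len(elements) == 1:
        return f"Chr{elements[0]}"
    return "Chr" + "+".join(elements)


# canonical karyotypes of the two focal species and the outgroup
def karyotype_P() -> KaryotypeConfig:
    return KaryotypeConfig("P", fusions=(("IL", "IR"),))


def karyotype_E() -> KaryotypeConfig:
    return KaryotypeConfig("E", fusions=(("IR", "X"),))


def karyotype_outgroup() -> KaryotypeConfig:
    return KaryotypeConfig("O", fusions=())


class GeneticMapModel:
    """Per-element monotone Marey functions (bp -> cM).

    Each element carries a piecewise-linear map anchored at 0 cM at the
    element start.  Chromosome-level quantities (total cM, crossover
    placement) are obtained by concatenating the member elements.
    """

    def __init__(self, knots: dict[str, tuple[np.ndarray, np.ndarray]]):
        self._knots = {}
        for name, (bp, cm) in knots.items():
            bp = np.asarray(bp, dtype=float)
            cm = np.asarray(cm, dtype=float)
            if bp.size != cm.size or bp.size < 2:
                raise ValueError(f"{name}: need >=2 matching knots")
            if cm[0] != 0.0 or np.any(np.diff(cm) < 0) or np.any(np.diff(bp) <= 0):
                raise ValueError(f"{name}: Marey function must start at 0 and be non-decreasing")
            self._knots[name] = (bp, cm)

    @classmethod
    def uniform(cls, lengths: dict[str, int], cm_per_element: float | dict[str, float]) -> "GeneticMapModel":
        knots = {}
        for name, L in lengths.items():
            total = cm_per_element[name] if isinstance(cm_per_element, dict) else cm_per_element
            knots[name] = (np.array([1.0, float(L)]), np.array([0.0, float(total)]))
        return cls(knots)

    @classmethod
    def centre_suppressed(
        cls,
        lengths: dict[str, int],
        total_cm: float | dict[str, float],
        centre_fraction: float = 0.5,
        centre_share: float = 0.1,
    ) -> "GeneticMapModel":
        """Maps with a recombination-poor centre, as in holocentric nematodes.

        The middle ``centre_fraction`` of each element receives only
        ``centre_share`` of the element's genetic length.
        """
        knots = {}
        for name, L in lengths.items():
            tot = total_cm[name] if isinstance(total_cm, dict) else total_cm
            a = (1.0 - centre_fraction) / 2.0
            bp = np.array([1.0, a * L, (1.0 - a) * L, float(L)])
            arm = tot * (1.0 - centre_share) / 2.0
            cm = np.array([0.0, arm, arm + tot * centre_share, tot])
            knots[name] = (bp, cm)
        return cls(knots)

    def elements(self) -> list[str]:
        return list(self._knots)

    def total_cm(self, element: str) -> float:
        return float(self._knots[element][1][-1])

    def cm_at(self, element: str, bp) -> np.ndarray:
        xs, cs = self._knots[element]
        return np.interp(np.asarray(bp, dtype=float), xs, cs)

    def bp_at(self, element: str, cm) -> np.ndarray:
        xs, cs = self._knots[element]
        # strictly increasing cM is required for a unique inverse; flat
        # stretches invert to their left edge, which is fine for sampling.
        return np.interp(np.asarray(cm, dtype=float), cs, xs)

    def chromosome_total_cm(self, elements: tuple[str, ...]) -> float:
        return sum(self.total_cm(e) for e in elements)

    def sample_crossover(self, elements: tuple[str, ...], rng: np.random.Generator) -> tuple[str, float]:
        """Draw one crossover position uniform in genetic distance.

        Returns the element and the bp position within that element.
        """
        totals = np.array([self.total_cm(e) for e in elements])
        u = rng.uniform(0.0, totals.sum())
        cum = np.cumsum(totals)
        idx = int(np.searchsorted(cum, u, side="right"))
        idx = min(idx, len(elements) - 1)
        within = u - (cum[idx - 1] if idx else 0.0)
        el = elements[idx]
        return el, float(self.bp_at(el, within))


@dataclass
class SpeciesGenomeModel:
    """A species' genome: elements + karyotype + (lazily built) sequence.

    Chromosome coordinates place fused elements head-to-tail, so the
    second element of a fusion starts at ``first.length + 1``.
    """

    config: KaryotypeConfig
    elements: dict[str, ChromosomeElement]
    seed: int = 0

    def __post_init__(self):
        missing = set(ELEMENT_NAMES) - set(self.elements)
        if missing:
            raise ValueError(f"missing elements: {sorted(missing)}")
        for a, b in self.config.fusions:
            if (a, b) == ("IL", "IR") and self.elements["IL"].length != self.config.breakpoint_bp:
                raise ValueError(
                    "IL length must equal the fusion breakpoint "
                    f"({self.elements['IL'].length} != {self.config.breakpoint_bp})"
                )

    def chromosomes(self) -> dict[str, tuple[str, ...]]:
        return {chromosome_name(c): c for c in self.config.chromosome_composition()}

    def chromosome_length(self, chrom: str) -> int:
        return sum(self.elements[e].length for e in self.chromosomes()[chrom])

    def element_offset(self, chrom: str, element: str) -> int:
        """0-based offset of an element within its chromosome."""
        off = 0
        for e in self.chromosomes()[chrom]:
            if e == element:
                return off
            off += self.elements[e].length
        raise KeyError(f"element {element} not on {chrom}")

    def locate(self, element: str, pos_in_element) -> tuple[str, np.ndarray]:
        """Map element coordinates to (chromosome, chromosome position)."""
        for chrom, comp in self.chromosomes().items():
            if element in comp:
                off = self.element_offset(chrom, element)
                return chrom, np.asarray(pos_in_element, dtype=int) + off
        raise KeyError(element)

    def to_chromosome_coords(self, table: pd.DataFrame, pos_col: str = "pos") -> pd.DataFrame:
        """Re-express an ``element``/position table on this karyotype's
        chromosome coordinates (columns ``chrom`` and ``pos_col``)."""
        out = table.copy()
        chroms = pd.Series(index=table.index, dtype=object)
        pos = pd.Series(index=table.index, dtype=int)
        for el, grp in table.groupby("element"):
            ch, cp = self.locate(el, grp[pos_col].to_numpy())
            chroms.loc[grp.index] = ch
            pos.loc[grp.index] = cp
        out["chrom"] = chroms
        out[pos_col] = pos
        return out.drop(columns=["element"])

    def element_sequences(self, alt_at_snps: bool = False) -> dict[str, str]:
        """Random but seed-reproducible element sequences.

        With ``alt_at_snps`` the diagnostic-SNP positions carry the
        alternative base, producing the second species' alleles on the
        shared coordinate system.
        """
        bases = np.frombuffer(b"ACGT", dtype="S1")
        seqs = {}
        for i, name in enumerate(ELEMENT_NAMES):
            el = self.elements[name]
            rng = np.random.default_rng(np.random.SeedSequence((self.seed, 7, i)))
            idx = rng.integers(0, 4, size=el.length)
            if alt_at_snps and el.snp_positions.size:
                # shift base by 1..3 so the alternative always differs
                shift = rng.integers(1, 4, size=el.snp_positions.size)
                j = el.snp_positions - 1
                idx[j] = (idx[j] + shift) % 4
            seqs[name] = bases[idx].tobytes().decode()
        return seqs

    def chromosome_sequences(self, alt_at_snps: bool = False) -> dict[str, str]:
        el_seqs = self.element_sequences(alt_at_snps=alt_at_snps)
        return {chrom: "".join(el_seqs[e] for e in comp) for chrom, comp in self.chromosomes().items()}


def build_species_pair(
    element_lengths: dict[str, int] | None = None,
    snp_density: float = 1 / 5000.0,
    gene_density: float = 1 / 50_000.0,
    seed: int = 0,
    config_p: KaryotypeConfig | None = None,
    config_e: KaryotypeConfig | None = None,
    gene_profile: str = "uniform",
) -> tuple[SpeciesGenomeModel, SpeciesGenomeModel, pd.DataFrame]:
    """Build the two species' genome models on a shared coordinate system.

    Diagnostic SNP and gene positions are drawn once per element (uniform
    at random; genes optionally centre-enriched via ``gene_profile =
    "centre"``) and shared by both species, so every coordinate is
    directly comparable.  Returns the two models plus a site table with
    element coordinates and the chromosome coordinates in each species.
    """
    lengths = dict(DEFAULT_ELEMENT_LENGTHS if element_lengths is None else element_lengths)
    if snp_density <= 0 or gene_density <= 0:
        raise ValueError("densities must be positive")
    if any(L <= 0 for L in lengths.values()):
        raise ValueError("element lengths must be positive")
    config_p = config_p or KaryotypeConfig("P", fusions=(("IL", "IR"),), breakpoint_bp=lengths["IL"])
    config_e = config_e or KaryotypeConfig("E", fusions=(("IR", "X"),), breakpoint_bp=lengths["IL"])

    elements: dict[str, ChromosomeElement] = {}
    for i, name in enumerate(ELEMENT_NAMES):
        L = lengths[name]
        rng = np.random.default_rng(np.random.SeedSequence((seed, 11, i)))
        n_snp = rng.binomial(L, snp_density)
        snps = np.sort(rng.choice(np.arange(1, L + 1), size=n_snp, replace=False))
        n_gene = rng.binomial(L, gene_density)
        if gene_profile == "centre":
            # triangular density peaking at the element centre
            raw = rng.triangular(1, L / 2, L, size=n_gene).astype(int)
            genes = np.unique(np.clip(raw, 1, L))
        else:
            genes = np.sort(rng.choice(np.arange(1, L + 1), size=n_gene, replace=False))
        elements[name] = ChromosomeElement(name, L, gene_positions=genes, snp_positions=snps)

    model_p = SpeciesGenomeModel(config_p, elements, seed=seed)
    model_e = SpeciesGenomeModel(config_e, elements, seed=seed)

    rows = []
    for name in ELEMENT_NAMES:
        el = elements[name]
        chrom_p, pos_p = model_p.locate(name, el.snp_positions)
        chrom_e, pos_e = model_e.locate(name, el.snp_positions)
        rows.append(
            pd.DataFrame(
                {
                    "element": name,
                    "pos_in_element": el.snp_positions,
                    "chrom_p": chrom_p,
                    "pos_p": pos_p,
                    "chrom_e": chrom_e,
                    "pos_e": pos_e,
                }
            )
        )
    sites = pd.concat(rows, ignore_index=True)
    return model_p, model_e, sites
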