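"""Chromosome-specific k-mer selection and FISH oligo design.

Canonical (strand-collapsed) 21-mers are counted per chromosome unit in
two genomes; the fused chromosome is split at the fusion breakpoint so
its two ancestral elements count as separate units.  Marker k-mers must
be abundant (> 50 copies) on the target unit in genome 1 AND on its
homologous unit in genome 2, and rare (< 50 copies) on every other unit
of both genomes.  Selected k-mers are merged into contigs by genomic
overlap and tiled with 20-24 bp oligos that pairwise overlap by at most
2 bp.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass


_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def canonical(kmer: str) -> str:
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def count_kmers(seq: str, k: int = 21, stranded: bool = False) -> Counter:
    """Canonical k-mer counts of one sequence; windows with N are skipped."""
    if len(seq) < k:
        raise ValueError(f"sequence shorter than k = {k}")
    seq = seq.upper()
    counts: Counter = Counter()
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        counts[kmer if stranded else canonical(kmer)] += 1
    return counts


@dataclass
class KmerIndex:
    """Per-(genome, chromosome-unit) canonical k-mer counts."""

    k: int
    counts: dict[tuple[str, str], Counter]  # (genome, unit) -> Counter

    def units(self, genome: str) -> list[str]:
        return [u for g, u in self.counts if g == genome]


def chromosome_kmer_counts(
    genomes: dict[str, dict[str, str]],
    k: int = 21,
    split: dict[tuple[str, str], tuple[int, str, str]] | None = None,
    stranded: bool = False,
) -> KmerIndex:
    """Count k-mers per chromosome unit in each genome.

    ``genomes`` maps genome name -> {chromosome: sequence}.  ``split``
    optionally splits a fused chromosome: (genome, chrom) -> (breakpoint
    bp, left unit name, right unit name), so the two ancestral elements
    are treated as different chromosomes.
    """
    if k % 2 == 0:
        raise ValueError("k must be odd so no k-mer is its own reverse complement")
    counts: dict[tuple[str, str], Counter] = {}
    for genome, chroms in genomes.items():
        for chrom, seq in chroms.items():
            if split and (genome, chrom) in split:
                bp, left, right = split[(genome, chrom)]
                parts = {left: seq[:bp], right: seq[bp:]}
            else:
                parts = {chrom: seq}
            for unit, sub in parts.items():
                counts[(genome, unit)] = count_kmers(sub, k, stranded=stranded)
    return KmerIndex(k=k, counts=counts)


def select_marker_kmers(
    index: KmerIndex,
    target_unit: str,
    homology: dict[str, str],
    genome1: str,
    genome2: str,
    min_on_target: int = 50,
    max_off_target: int = 50,
) -> set[str]:
    """Chromosome-specific marker k-mers for one target unit.

    Keeps k-mers occurring more than ``min_on_target`` times on the
    target unit in ``genome1`` and on its homolog in ``genome2``, and
    fewer than ``max_off_target`` times on every other unit of both
    genomes (thresholds are exclusive on both sides, matching the
    "more than 50 / less than 50" rule).
    """
    if target_unit not in homology:
        raise ValueError(f"no homolog defined for target unit {target_unit!r}")
    homolog = homology[target_unit]
    on1 = index.counts[(genome1, target_unit)]
    on2 = index.counts[(genome2, homolog)]
    candidates = {km for km, c in on1.items() if c > min_on_target and on2.get(km, 0) > min_on_target}
    others = [
        counter
        for (g, u), counter in index.counts.items()
        if not (g == genome1 and u == target_unit) and not (g == genome2 and u == homolog)
    ]
    return {km for km in candidates if all(c.get(km, 0) < max_off_target for c in others)}


@dataclass
class ProbeCandidate:
    sequence: str
    unit: str
    start: int  # 1-based position on the unit
    contig_start: int
    contig_end: int

    def __post_init__(self):
        if not (20 <= len(self.sequence) <= 24):
            raise ValueError("oligo length must be 20-24 bp")


def _kmer_occurrences(seq: str, kmers: set[str], k: int) -> list[int]:
    """0-based start positions where a selected (canonical) k-mer occurs."""
    seq = seq.upper()
    hits = []
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        if canonical(kmer) in kmers:
            hits.append(i)
    return hits


def design_oligos(
    kmers: set[str],
    unit_sequence: str,
    unit: str,
    k: int = 21,
    length_range: tuple[int, int] = (20, 24),
    max_overlap: int = 2,
) -> list[ProbeCandidate]:
    """Tile marker-k-mer contigs with non-overlapping oligos.

    Occurrences of the selected k-mers on the target unit are merged
    into contigs wherever they overlap or abut; each contig is tiled
    left-to-right greedily with oligos of the maximum feasible length
    such that no two oligos overlap by more than ``max_overlap`` bp.
    """
    if not kmers:
        return []
    lo, hi = length_range
    hits = _kmer_occurrences(unit_sequence, kmers, k)
    if not hits:
        return []
    # merge overlapping/adjacent k-mer intervals into contigs
    contigs: list[tuple[int, int]] = []
    start = hits[0]
    end = hits[0] + k
    for h in hits[1:]:
        if h <= end:
            end = max(end, h + k)
        else:
            contigs.append((start, end))
            start, end = h, h + k
    contigs.append((start, end))

    probes: list[ProbeCandidate] = []
    for cs, ce in contigs:
        cursor = cs
        while ce - cursor >= lo:
            olen = min(hi, ce - cursor)
            probes.append(
                ProbeCandidate(
                    sequence=unit_sequence[cursor : cursor + olen],
                    unit=unit,
                    start=cursor + 1,
                    contig_start=cs + 1,
                    contig_end=ce,
                )
            )
            # next oligo may reuse at most max_overlap trailing bases
            cursor = cursor + olen - max_overlap
    return probes
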