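"""File interchange: FASTA genomes, VCF allele depths, BED segments, TSV
matrices.

The simulated coordinate system names the seven ancestral elements as
contigs.  All text positions are 1-based inclusive except BED, which is
0-based half-open.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd

from .simulate import SimulatedIndividual


def write_fasta(sequences: dict[str, str], path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_allele_depths_vcf(
    tables: dict[str, pd.DataFrame],
    path: str | os.PathLike,
    contig_lengths: dict[str, int],
) -> None:
    """Multi-sample VCF 4.2 with per-sample AD (ref,alt) fields.

    Table columns: ``element`` (or ``chrom``), ``pos``, ``ref_count``,
    ``alt_count``.  Allele columns ``ref``/``alt`` are used when present;
    otherwise placeholder bases are written (the counts, not the bases,
    carry the information here).
    """
    samples = sorted(tables)
    frames = []
    for s in samples:
        t = tables[s].rename(columns={"element": "chrom"})
        frames.append(t.set_index(["chrom", "pos"])[["ref_count", "alt_count"]].add_prefix(f"{s}__"))
    wide = pd.concat(frames, axis=1).sort_index()
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c, L in contig_lengths.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for (chrom, pos), row in wide.iterrows():
            fields = [chrom, str(int(pos)), ".", "A", "C", ".", ".", ".", "AD"]
            for s in samples:
                r = row.get(f"{s}__ref_count", np.nan)
                a = row.get(f"{s}__alt_count", np.nan)
                fields.append("." if not np.isfinite(r) else f"{int(r)},{int(a)}")
            fh.write("\t".join(fields) + "\n")


def read_allele_depths_vcf(path: str | os.PathLike) -> dict[str, pd.DataFrame]:
    """Read AD fields back into per-sample allele-depth tables."""
    import pysam

    vf = pysam.VariantFile(str(path))
    samples = list(vf.header.samples)
    rows: dict[str, list] = {s: [] for s in samples}
    for rec in vf:
        for s in samples:
            ad = rec.samples[s].get("AD")
            if ad is None or ad[0] is None:
                continue
            rows[s].append((rec.chrom, rec.pos, int(ad[0]), int(ad[1])))
    return {
        s: pd.DataFrame(rows[s], columns=["element", "pos", "ref_count", "alt_count"])
        for s in samples
    }


def truth_segments(panel: list[SimulatedIndividual]) -> pd.DataFrame:
    """Long table of every ancestry segment of every chromosome copy."""
    rows = []
    for ind in panel:
        for el, copies in ind.haplotypes.items():
            for ci, copy in enumerate(copies):
                for s, e, o in copy:
                    rows.append((ind.id, el, ci, s, e, o))
    return pd.DataFrame(rows, columns=["individual", "element", "copy", "start", "end", "origin"])


def write_truth_bed(panel: list[SimulatedIndividual], path: str | os.PathLike) -> None:
    """Ancestry truth segments as BED (0-based half-open), one row per segment."""
    seg = truth_segments(panel)
    bed = pd.DataFrame(
        {
            "chrom": seg["element"],
            "start": seg["start"] - 1,
            "end": seg["end"],
            "name": seg["individual"] + "|copy" + seg["copy"].astype(str) + "|" + seg["origin"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_truth_bed(path: str | os.PathLike) -> pd.DataFrame:
    bed = pd.read_csv(path, sep="\t", header=None, names=["chrom", "start", "end", "name"])
    name = bed["name"].str.split("|", expand=True)
    return pd.DataFrame(
        {
            "individual": name[0],
            "element": bed["chrom"],
            "copy": name[1].str.removeprefix("copy").astype(int),
            "start": bed["start"] + 1,
            "end": bed["end"],
            "origin": name[2],
        }
    )


def phenotype_table(panel: list[SimulatedIndividual]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual": [i.id for i in panel],
            "role": [i.role for i in panel],
            "fertile": [i.fertile for i in panel],
            "n_progeny": [i.n_progeny for i in panel],
            "copy_number_IR": [len(i.haplotypes.get("IR", [1, 1])) for i in panel],
        }
    )


def write_matrix_tsv(matrix: pd.DataFrame, path: str | os.PathLike) -> None:
    """Individuals x windows matrix with 'chrom:start' column labels."""
    out = matrix.copy()
    if isinstance(out.columns, pd.MultiIndex):
        out.columns = [f"{c}:{s}" for c, s in out.columns]
    out.to_csv(path, sep="\t", index_label="individual")


def read_matrix_tsv(path: str | os.PathLike) -> pd.DataFrame:
    mat = pd.read_csv(path, sep="\t", index_col=0)
    parts = [c.rsplit(":", 1) for c in mat.columns]
    mat.columns = pd.MultiIndex.from_tuples(
        [(c, int(s)) for c, s in parts], names=["chrom", "start"]
    )
    return mat


def write_panel(
    panel: list[SimulatedIndividual],
    outdir: str | os.PathLike,
    depth_tables: dict[str, pd.DataFrame] | None = None,
    contig_lengths: dict[str, int] | None = None,
    genomes: dict[str, dict[str, str]] | None = None,
) -> dict[str, Path]:
    """Write a simulated panel to disk; returns the paths written.

    Always writes the phenotype TSV and the ancestry-truth BED; allele
    depths (VCF) and genome FASTAs are written when supplied.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["phenotypes"] = outdir / "phenotypes.tsv"
    phenotype_table(panel).to_csv(paths["phenotypes"], sep="\t", index=False)
    paths["truth"] = outdir / "truth_segments.bed"
    write_truth_bed(panel, paths["truth"])
    if depth_tables is not None:
        if contig_lengths is None:
            raise ValueError("contig_lengths required to write a VCF")
        paths["vcf"] = outdir / "allele_depths.vcf"
        write_allele_depths_vcf(depth_tables, paths["vcf"], contig_lengths)
    if genomes:
        for name, seqs in genomes.items():
            p = outdir / f"genome_{name}.fasta"
            write_fasta(seqs, p)
            paths[f"genome_{name}"] = p
    return paths
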