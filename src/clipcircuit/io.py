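"""Readers and writers for BED6/BED12, GFF3, FASTA, and tabular files.

Internal coordinates are always 0-based half-open; GFF3's 1-based closed
convention is converted here and nowhere else. Tabular outputs are plain
TSV with a header row so every stage is diff-able.
"""

from __future__ import annotations

import os
from typing import Sequence

import pandas as pd
import pyranges as pr
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, FeatureAnnotation
from .readsets import ReadSet

#: GFF3 feature types mapped to internal feature classes.
GFF3_TYPE_TO_CLASS = {
    "lnc_RNA": "lncRNA",
    "lncRNA": "lncRNA",
    "three_prime_UTR": "three_prime_utr",
    "CDS": "cds",
    "exon": "exon",
    "intron": "intron",
    "miRNA": "mirna_locus",
    "rRNA_repeat": "rrna_repeat",
}
CLASS_TO_GFF3_TYPE = {
    "lncRNA": "lnc_RNA",
    "three_prime_utr": "three_prime_UTR",
    "cds": "CDS",
    "exon": "exon",
    "intron": "intron",
    "mirna_locus": "miRNA",
    "rrna_repeat": "rRNA_repeat",
    "other": "region",
}


# ---------------------------------------------------------------------------
# BED6 reads

def read_reads_bed(path: str | os.PathLike, dedup: bool = False) -> ReadSet:
    """Read stranded CLIP tags from a BED6 file.

    Raises ``ValueError`` naming the offending 1-based line for missing
    strand or malformed coordinates. ``dedup=True`` collapses identical
    (chrom, start, end, strand) tuples to one read.
    """
    chroms, starts, ends, strands = [], [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(
                    f"{path}: line {lineno}: BED6 requires 6 columns "
                    f"(strand missing?), got {len(fields)}"
                )
            chrom, s, e, _name, _score, strand = fields[:6]
            try:
                start, end = int(s), int(e)
            except ValueError as exc:
                raise ValueError(
                    f"{path}: line {lineno}: malformed coordinates {s!r}/{e!r}"
                ) from exc
            if strand not in ("+", "-"):
                raise ValueError(
                    f"{path}: line {lineno}: strand must be '+' or '-', got {strand!r}"
                )
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            chroms.append(chrom)
            starts.append(start)
            ends.append(end)
            strands.append(strand)
    rs = ReadSet(chroms, starts, ends, strands)
    return rs.deduplicated() if dedup else rs


def write_reads_bed(reads: ReadSet, path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        for c, s, e, st in zip(reads.chroms, reads.starts, reads.ends, reads.strands):
            fh.write(f"{c}\t{s}\t{e}\t.\t0\t{st}\n")


# ---------------------------------------------------------------------------
# Annotations (GFF3 / BED12)

def read_annotations(path: str | os.PathLike, dialect: str = "gff3") -> list[FeatureAnnotation]:
    """Read feature annotations from GFF3 or BED12.

    GFF3 lines sharing an ``ID`` become blocks of one multi-block feature;
    BED12 block columns are expanded. Unrecognised GFF3 types map to class
    ``other``.
    """
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown annotation dialect {dialect!r}")


def _read_gff3(path) -> list[FeatureAnnotation]:
    df = pr.read_gff3(str(path)).df
    if "ID" not in df.columns:
        raise ValueError(f"{path}: GFF3 features need ID attributes")
    feats: list[FeatureAnnotation] = []
    for fid, grp in df.groupby("ID", sort=False):
        first = grp.iloc[0]
        fclass = GFF3_TYPE_TO_CLASS.get(str(first["Feature"]), "other")
        gene = str(first["gene_id"]) if "gene_id" in grp.columns and pd.notna(first.get("gene_id")) else str(fid)
        blocks = []
        for _, row in grp.iterrows():
            start, end = int(row["Start"]), int(row["End"])
            if end <= start:
                raise ValueError(f"{path}: feature {fid}: end <= start after conversion")
            blocks.append(GenomicInterval(str(row["Chromosome"]), start, end, str(row["Strand"])))
        feats.append(FeatureAnnotation(str(fid), gene, fclass, tuple(blocks)))
    return feats


def _read_bed12(path) -> list[FeatureAnnotation]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "thickStart", "thickEnd", "rgb", "blockCount", "blockSizes", "blockStarts",
    ]
    df = pd.read_csv(path, sep="\t", header=None, names=cols, comment="#")
    feats = []
    for _, row in df.iterrows():
        sizes = [int(x) for x in str(row.blockSizes).rstrip(",").split(",")]
        offsets = [int(x) for x in str(row.blockStarts).rstrip(",").split(",")]
        blocks = [
            GenomicInterval(row.chrom, int(row.start) + o, int(row.start) + o + sz, row.strand)
            for o, sz in zip(offsets, sizes)
        ]
        feats.append(FeatureAnnotation(str(row["name"]), str(row["name"]), "other", tuple(blocks)))
    return feats


def write_gff3(features: Sequence[FeatureAnnotation], path: str | os.PathLike,
               source: str = "clipcircuit") -> None:
    """Write features as GFF3 (one line per block, shared ID)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            ftype = CLASS_TO_GFF3_TYPE.get(f.feature_class, "region")
            for b in f.blocks:
                fh.write(
                    f"{b.chrom}\t{source}\t{ftype}\t{b.start + 1}\t{b.end}\t.\t"
                    f"{b.strand}\t.\tID={f.feature_id};gene_id={f.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# Sequences and miRNA tables

def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    """Transcript sequences keyed by record id, uppercased DNA."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: dict[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_mirna_table(path: str | os.PathLike) -> pd.DataFrame:
    """TSV with columns family_id, mirna_id, sequence (mature, 5'->3')."""
    df = pd.read_csv(path, sep="\t")
    required = {"family_id", "mirna_id", "sequence"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    return df


# ---------------------------------------------------------------------------
# Contrast tables

def read_contrast_table(path: str | os.PathLike, label: str | None = None) -> pd.DataFrame:
    """Per-gene expression contrast: columns gene_id, log2fc, padj.

    Sign convention: log2fc = log2(first-named condition / second-named).
    """
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "log2fc", "padj"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df["gene_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate gene_ids")
    if not pd.Series(df["log2fc"]).map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError(f"{path}: non-finite log2fc")
    df = df.copy()
    df.attrs["contrast_label"] = label or ""
    return df


def write_tsv(df: pd.DataFrame, path: str | os.PathLike, float_format: str = "%.6g") -> None:
    df.to_csv(path, sep="\t", index=False, float_format=float_format)
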