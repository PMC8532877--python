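"""Readers and writers for the plain-text formats the pipeline exchanges.

FASTA goes through Biopython, GTF parsing through gffutils' record
iterator, tables through pandas.  Internal coordinates are 0-based
half-open; GTF is written 1-based inclusive and BED12 0-based half-open,
as the two formats define.
"""

from __future__ import annotations

import os
from collections.abc import Iterable, Mapping

import gffutils.iterators
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .models import TranscriptModel


# ---------------------------------------------------------------------- FASTA

def write_fasta(sequences: Mapping[str, str | bytearray], path: str | os.PathLike) -> None:
    records = [
        SeqRecord(Seq(bytes(s).decode() if isinstance(s, (bytes, bytearray)) else s),
                  id=name, description="")
        for name, s in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ------------------------------------------------------------------------ GTF

def write_gtf(transcripts: Iterable[TranscriptModel], path: str | os.PathLike,
              source: str = "capriseq") -> None:
    with open(path, "w") as fh:
        for t in transcripts:
            gid = t.gene_id or t.transcript_id
            attrs = f'gene_id "{gid}"; transcript_id "{t.transcript_id}";'
            s, e = t.span
            fh.write("\t".join([t.chromosome, source, "transcript", str(s + 1),
                                str(e), ".", t.strand, ".", attrs]) + "\n")
            for (es, ee) in t.exons:
                fh.write("\t".join([t.chromosome, source, "exon", str(es + 1),
                                    str(ee), ".", t.strand, ".", attrs]) + "\n")


def read_gtf(path: str | os.PathLike) -> list[TranscriptModel]:
    """Load transcript models (exon features grouped by transcript_id)."""
    exons: dict[str, list[tuple[int, int]]] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in gffutils.iterators.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        tid = feat.attributes["transcript_id"][0]
        gid = feat.attributes.get("gene_id", [tid])[0]
        exons.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta[tid] = (feat.seqid, feat.strand, gid)
    out = []
    for tid in sorted(exons):
        chrom, strand, gid = meta[tid]
        out.append(TranscriptModel(tid, chrom, strand, sorted(exons[tid]), gene_id=gid))
    return out


# ---------------------------------------------------------------------- BED12

def write_bed12(rows: Iterable[tuple[str, TranscriptModel]] | Iterable[TranscriptModel],
                path: str | os.PathLike) -> None:
    """Write transcript models (or (name, model) pairs) as BED12 lines."""
    with open(path, "w") as fh:
        for item in rows:
            name, t = item if isinstance(item, tuple) else (item.transcript_id, item)
            s, e = t.span
            sizes = ",".join(str(ee - es) for es, ee in t.exons) + ","
            starts = ",".join(str(es - s) for es, ee in t.exons) + ","
            fh.write("\t".join([
                t.chromosome, str(s), str(e), name, "0", t.strand,
                str(s), str(e), "0", str(len(t.exons)), sizes, starts]) + "\n")


def read_bed12(path: str | os.PathLike) -> list[TranscriptModel]:
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track")):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = [(start + o, start + o + sz) for o, sz in zip(offsets, sizes)]
            out.append(TranscriptModel(name, chrom, strand, exons))
    return out


# ------------------------------------------------------------------------ TSV

def write_tsv(df: pd.DataFrame, path: str | os.PathLike, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_tsv(path: str | os.PathLike, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kwargs)
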