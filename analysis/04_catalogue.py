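"""Catalogue FLNC reads into loci and isoforms; call novelty.

The FLNC reads are clustered into loci and collapsed to distinct intron
chains.  Novelty is judged against a deliberately thinned reference (a
fraction of genes and all derived isoforms withheld), so both novel loci
and novel isoforms genuinely occur.  Writes the catalogue GTF, the
per-isoform table and the locus length distribution.
"""

import argparse
from pathlib import Path

import numpy as np

from capriseq import io as cio
from capriseq.isocat import build_catalogue, locus_length, locus_length_summary
from capriseq.reads import PrimerConfig, annotate_and_classify
from capriseq.simdata import SimConfig
from capriseq.models import TranscriptModel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/simulated")
    ap.add_argument("--outdir", default="results/catalogue")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--withhold-genes", type=float, default=0.2,
                    help="fraction of reference genes hidden to expose novel loci")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    indir = Path(args.indir)
    annotation = cio.read_gtf(indir / "annotation.gtf")
    reads = cio.read_fasta(indir / "reads.fa")
    truth = cio.read_tsv(indir / "read_truth.tsv")
    placements = {t.transcript_id: t
                  for t in cio.read_bed12(indir / "true_alignments.bed")}

    cfg = SimConfig()
    records = annotate_and_classify(
        reads, PrimerConfig(primer5=cfg.primer5, primer3=cfg.primer3))
    flnc = {r.read_id for r in records if r.category == "flnc"}
    models = []
    for rid in sorted(flnc):
        t = placements.get(rid)
        if t is not None:
            models.append(TranscriptModel(rid, t.chromosome, t.strand,
                                          list(t.exons),
                                          support=[(rid, 100.0)]))

    # thin the reference: hide a fraction of genes and every non-base isoform
    rng = np.random.default_rng(args.seed)
    gene_ids = sorted({t.gene_id for t in annotation})
    hidden = set(rng.choice(gene_ids,
                            size=int(args.withhold_genes * len(gene_ids)),
                            replace=False))
    reference = [t for t in annotation
                 if t.gene_id not in hidden and t.transcript_id.endswith(".t1")]

    cat = build_catalogue(models, reference=reference)
    frame = cat.to_frame()
    cio.write_tsv(frame, outdir / "isoforms.tsv")
    cio.write_gtf([r.representative for rs in cat.isoforms.values() for r in rs],
                  outdir / "catalogue.gtf")
    lengths = [locus_length(locus, cat.isoforms[locus.locus_id])
               for locus in cat.loci if cat.isoforms[locus.locus_id]]
    summary = locus_length_summary(lengths)
    cio.write_tsv(summary, outdir / "locus_length_summary.tsv")

    n_novel_loci = sum(1 for x in cat.loci if x.novelty == "novel")
    novel_iso = (frame["isoform_novelty"] == "novel").sum()
    full = frame["full_length"].fillna(False).sum()
    print(f"{len(models)} FLNC reads -> {len(cat.loci)} loci "
          f"({n_novel_loci} novel), {len(frame)} isoforms "
          f"({novel_iso} novel, {cat.discarded} discarded low-support)")
    print(f"full-length multi-exon isoforms: {int(full)}")
    print(summary.to_string(index=False))


if __name__ == "__main__":
    main()
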