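"""Alignment quality triage: pre- vs post-correction rounds and merge.

Long-read placements start noisy and improve after short-read error
correction.  Here the two rounds are emulated from the true placements
by drawing a per-read raw error rate and shrinking it for the corrected
round; the table then shows the four categories per round and the
best-of-both merge, plus exon coverage of the annotation.
"""

import argparse
from pathlib import Path

import numpy as np

from capriseq import io as cio
from capriseq.alignqc import (AlignmentRecord, category_table, classify_all,
                              exon_coverage, merge_rounds)


def degraded_round(models, read_lengths, error, rng):
    out = []
    for t in models:
        aligned = t.spliced_length
        e = float(error(rng))
        out.append(AlignmentRecord(
            read_id=t.transcript_id.split("/")[0], chromosome=t.chromosome,
            strand=t.strand, blocks=list(t.exons),
            matches=int(aligned * (1.0 - e)), aligned_columns=aligned,
            read_length=read_lengths.get(t.transcript_id.split("/")[0], aligned)))
    return out


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/simulated")
    ap.add_argument("--outdir", default="results/alignqc")
    ap.add_argument("--seed", type=int, default=7)
    ap.add_argument("--pid-threshold", type=float, default=90.0)
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    placements = cio.read_bed12(Path(args.indir) / "true_alignments.bed")
    reads = cio.read_fasta(Path(args.indir) / "reads.fa")
    read_ids = sorted(reads)
    lengths = {rid: len(s) for rid, s in reads.items()}

    rng = np.random.default_rng(args.seed)
    pre = degraded_round(placements, lengths,
                         lambda r: r.uniform(0.02, 0.18), rng)
    post = degraded_round(placements, lengths,
                          lambda r: r.uniform(0.002, 0.04), rng)
    pre_cls = classify_all(pre, read_ids, args.pid_threshold)
    post_cls = classify_all(post, read_ids, args.pid_threshold)
    merged = merge_rounds(pre_cls, post_cls)

    table = category_table({"pre_correction": pre_cls,
                            "post_correction": post_cls, "merge": merged})
    cio.write_tsv(table.rename_axis("category").reset_index(),
                  outdir / "alignment_categories.tsv")
    print(table.to_string())

    annotation = cio.read_gtf(Path(args.indir) / "annotation.gtf")
    mapped = [rec for cat, rec in merged.values() if rec is not None
              and cat == "high_quality"]
    cov, hist = exon_coverage(mapped, annotation)
    cio.write_tsv(cov, outdir / "exon_coverage.tsv")
    print("\nexon coverage histogram:")
    print(hist.to_string())


if __name__ == "__main__":
    main()
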