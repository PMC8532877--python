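"""Score coding potential and filter lncRNA candidates.

Every catalogued isoform sequence is scanned for ORFs (>= 100 aa), given
a Fickett-based coding probability, and run through the conjunctive
lncRNA filter (>= 200 nt, probability <= 0.5, no protein-database hit).
The simulated transcripts are genomic fragments rather than true mRNAs,
so most behave like non-coding sequence — which is exactly what the
filter should report.
"""

import argparse
from pathlib import Path

import pandas as pd

from capriseq import io as cio
from capriseq.coding import CodingModel, assess, find_orfs
from capriseq.models import TranscriptModel


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/simulated")
    ap.add_argument("--outdir", default="results/coding")
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    genome = {k: bytearray(v.encode())
              for k, v in cio.read_fasta(Path(args.indir) / "genome.fa").items()}
    annotation = cio.read_gtf(Path(args.indir) / "annotation.gtf")
    model = CodingModel.load()

    rows = []
    orf_rows = []
    for t in annotation:
        seq = t.spliced_sequence(genome)
        for o in find_orfs(seq, t.transcript_id, min_aa=100):
            orf_rows.append({"isoform_id": t.transcript_id, "frame": o.frame,
                             "start": o.start, "end": o.end,
                             "aa_length": o.aa_length,
                             "completeness": o.completeness})
        a = assess(t.transcript_id, seq, protein_db_hit=False, model=model)
        rows.append({"isoform_id": a.isoform_id, "length": a.length,
                     "coding_probability": round(a.coding_probability, 4),
                     "protein_db_hit": a.protein_db_hit,
                     "is_lncRNA": a.is_lncRNA})

    assessment = pd.DataFrame(rows)
    cio.write_tsv(assessment, outdir / "coding_assessment.tsv")
    cio.write_tsv(pd.DataFrame(orf_rows), outdir / "orfs.tsv")
    print(f"{len(assessment)} isoforms assessed; "
          f"{len(orf_rows)} ORFs >= 100 aa; "
          f"{int(assessment['is_lncRNA'].sum())} lncRNA candidates "
          f"(median coding probability "
          f"{assessment['coding_probability'].median():.3f})")


if __name__ == "__main__":
    main()
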