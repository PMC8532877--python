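"""Enumerate splicing events, polyadenylation sites and fusion reads.

AS events compare the collapsed isoforms within each catalogued locus;
APA clusters the FLNC 3'-end positions per locus; fusion candidates come
from reads whose two fragments align to different loci (the simulated
chimeras).
"""

import argparse
from pathlib import Path

import pandas as pd

from capriseq import io as cio
from capriseq.events import (as_summary, detect_apa, detect_fusions,
                             enumerate_as_events, events_frame, SplitSegment)
from capriseq.isocat import build_catalogue
from capriseq.models import TranscriptModel
from capriseq.reads import PrimerConfig, annotate_and_classify
from capriseq.simdata import SimConfig


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--indir", default="results/simulated")
    ap.add_argument("--outdir", default="results/events")
    ap.add_argument("--apa-window", type=int, default=20)
    args = ap.parse_args()
    outdir = Path(args.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    indir = Path(args.indir)
    reads = cio.read_fasta(indir / "reads.fa")
    placements = {t.transcript_id: t
                  for t in cio.read_bed12(indir / "true_alignments.bed")}
    cfg = SimConfig()
    records = annotate_and_classify(
        reads, PrimerConfig(primer5=cfg.primer5, primer3=cfg.primer3))
    flnc = {r.read_id for r in records if r.category == "flnc"}
    models = [TranscriptModel(rid, p.chromosome, p.strand, list(p.exons),
                              support=[(rid, 100.0)])
              for rid, p in sorted(placements.items()) if rid in flnc]
    cat = build_catalogue(models)

    all_events = []
    apa_rows = []
    for locus in cat.loci:
        isoforms = cat.isoforms[locus.locus_id]
        all_events.extend(enumerate_as_events(isoforms, locus.locus_id))
        ends = [t.three_prime_end() for t in locus.transcripts]
        sites, is_apa = detect_apa(ends, locus.locus_id, window=args.apa_window)
        for s in sites:
            apa_rows.append({"locus_id": s.locus_id, "position": s.position,
                             "support": s.support, "apa_locus": is_apa})

    counts, ir_fraction = as_summary(all_events)
    cio.write_tsv(events_frame(all_events), outdir / "as_events.tsv")
    cio.write_tsv(pd.DataFrame(apa_rows), outdir / "apa_sites.tsv")

    # fusions from split placements: chimeric reads appear in the BED as
    # read/1 and read/2; their read-coordinate spans follow the simulated
    # layout primer5 + fragment1 + primer5 + fragment2 + polyA + primer3
    p5len = len(cfg.primer5)
    parts: dict[str, dict[int, TranscriptModel]] = {}
    for name, p in placements.items():
        if "/" in name:
            rid, k = name.split("/")
            parts.setdefault(rid, {})[int(k)] = p
    split_inputs = {}
    for rid, segs in parts.items():
        p1, p2 = segs[1], segs[2]
        l1, l2 = p1.spliced_length, p2.spliced_length
        split_inputs[rid] = (len(reads[rid]), [
            SplitSegment(p5len, p5len + l1,
                         f"{p1.chromosome}:{p1.span[0] // 5000}"),
            SplitSegment(2 * p5len + l1, 2 * p5len + l1 + l2,
                         f"{p2.chromosome}:{p2.span[0] // 5000}")])
    fusions = detect_fusions(split_inputs)
    cio.write_tsv(pd.DataFrame([{
        "read_id": f.read_id, "partner_5prime": f.partner_5prime,
        "partner_3prime": f.partner_3prime,
        "breakpoints": f"{f.breakpoints[0]}-{f.breakpoints[1]}"}
        for f in fusions]), outdir / "fusion_candidates.tsv")

    n_apa_loci = len({r["locus_id"] for r in apa_rows if r["apa_locus"]})
    ir_txt = f"{ir_fraction:.3f}" if ir_fraction is not None else "n/a"
    print(f"AS events: {counts}  IR fraction: {ir_txt}")
    print(f"APA loci (>=2 supported sites): {n_apa_loci}")
    print(f"fusion candidates: {len(fusions)}")


if __name__ == "__main__":
    main()
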