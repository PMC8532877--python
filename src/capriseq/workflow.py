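"""Closed-loop pipeline drivers over the synthetic data.

These helpers wire the stages together the way the analysis scripts run
them: simulate, classify reads, build transcript models from the
surviving FLNC placements, catalogue, and score everything against the
generator's truth.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from . import isocat, reads as readsmod
from .alignqc import AlignmentRecord
from .events import SplitSegment, detect_fusions
from .models import TranscriptModel
from .simdata import SimConfig, TruthSet, gen_annotation, gen_genome, sim_flnc_reads


@dataclass
class SimRun:
    """One simulated dataset with its intermediate products."""

    config: SimConfig
    genome: dict[str, bytearray]
    transcripts: list[TranscriptModel]
    truth: TruthSet
    reads: dict[str, str]
    labels: pd.DataFrame


def run_simulation(config: SimConfig) -> SimRun:
    genome = gen_genome(config)
    transcripts, truth = gen_annotation(genome, config)
    reads, _, labels = sim_flnc_reads(genome, transcripts, truth, config)
    return SimRun(config, genome, transcripts, truth, reads, labels)


def true_alignment_records(run: SimRun, read_ids: list[str] | None = None
                           ) -> list[AlignmentRecord]:
    """Perfect-placement alignment records from the truth blocks.

    Each non-chimeric read maps where the generator put it, with every
    aligned column a match (local PID 100); primers/polyA stay unaligned
    so the global PID falls below the local one.
    """
    wanted = set(read_ids) if read_ids is not None else None
    out = []
    for rid, rt in run.truth.reads.items():
        if wanted is not None and rid not in wanted:
            continue
        read_len = len(run.reads[rid])
        for seg in rt.segments:
            aligned = sum(e - s for s, e in seg.blocks)
            # sequencing indels can leave the read a little shorter than
            # its source blocks; matches can never exceed the read
            out.append(AlignmentRecord(
                read_id=rid, chromosome=seg.chromosome, strand=seg.strand,
                blocks=list(seg.blocks), matches=min(aligned, read_len),
                aligned_columns=aligned, read_length=read_len))
    return out


def flnc_transcript_models(run: SimRun,
                           classified: list[readsmod.ReadRecord] | None = None
                           ) -> list[TranscriptModel]:
    """One transcript model per FLNC read, placed at its true alignment.

    ``classified`` defaults to running the read classifier; only reads
    called FLNC contribute, each supporting itself at local PID 100.
    """
    if classified is None:
        primers = readsmod.PrimerConfig(primer5=run.config.primer5,
                                        primer3=run.config.primer3)
        classified = readsmod.annotate_and_classify(run.reads, primers)
    flnc = {r.read_id for r in classified if r.category == "flnc"}
    models = []
    for rid in sorted(flnc):
        rt = run.truth.reads.get(rid)
        if rt is None or len(rt.segments) != 1 or not rt.segments[0].blocks:
            continue
        seg = rt.segments[0]
        models.append(TranscriptModel(
            rid, seg.chromosome, seg.strand, list(seg.blocks),
            gene_id=seg.gene_id, support=[(rid, 100.0)]))
    return models


def catalogue_closed_loop(config: SimConfig
                          ) -> tuple[SimRun, isocat.Catalogue]:
    """Simulate, classify, and catalogue the FLNC reads (no reference)."""
    run = run_simulation(config)
    models = flnc_transcript_models(run)
    return run, isocat.build_catalogue(models)


def fusion_candidates_from_truth(run: SimRun):
    """Run fusion detection on every read's true split placements.

    Loci are identified by the true gene ids, so recall against the
    chimera truth labels is directly measurable.
    """
    inputs = {}
    for rid, rt in run.truth.reads.items():
        if not rt.segments:
            continue
        segs = [SplitSegment(s.read_span[0], s.read_span[1], s.gene_id)
                for s in rt.segments]
        inputs[rid] = (len(run.reads[rid]), segs)
    return detect_fusions(inputs)


def recovered_chain_sets(catalogue: isocat.Catalogue
                         ) -> set[tuple[str, str, tuple]]:
    """(chromosome, strand, intron chain) keys of the catalogued isoforms."""
    out = set()
    for records in catalogue.isoforms.values():
        for r in records:
            rep = r.representative
            out.add((rep.chromosome, rep.strand, rep.intron_chain))
    return out


def simulated_chain_sets(truth: TruthSet) -> set[tuple[str, str, tuple]]:
    return {(t.chromosome, t.strand, t.intron_chain)
            for t in truth.transcripts()}
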