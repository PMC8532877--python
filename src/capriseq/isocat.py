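"""Transcript cataloguing: loci clustering, isoform collapse, novelty calls.

The clustering rule links two aligned transcripts when they run on the
same strand, their genomic spans overlap by at least 20% (of the shorter
span by default) and at least one exon pair overlaps by more than 20% of
the shorter exon; loci are the connected components of that relation.
Within a locus, transcripts with identical intron chains are redundant
and the longest one represents them; mono-exon transcripts merge by
containment.  Novelty is judged against a reference annotation: a locus
is novel when it has no same-strand reference overlap of at least 20% of
its span, and an isoform is novel when it carries any splice site absent
from the reference (or, for mono-exon, is not an annotated single exon),
subject to the read-support rule (two FLNCs, or one with local PID above
99).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Interval, IsoformRecord, Locus, TranscriptModel, interval_overlap


# ------------------------------------------------------------------ loci

def _span_denominator(a: TranscriptModel, b: TranscriptModel, mode: str) -> float:
    la, lb = a.span_length, b.span_length
    if mode == "shorter":
        return min(la, lb)
    if mode == "longer":
        return max(la, lb)
    if mode == "union":
        return max(a.span[1], b.span[1]) - min(a.span[0], b.span[0])
    raise ValueError(f"unknown overlap denominator mode {mode!r}")


def transcripts_linked(a: TranscriptModel, b: TranscriptModel,
                       span_threshold: float = 0.20,
                       exon_threshold: float = 0.20,
                       denominator: str = "shorter") -> bool:
    """Direct same-locus link between two transcript models.

    Same strand AND span overlap >= ``span_threshold`` of the denominator
    span AND at least one exon pair overlapping strictly more than
    ``exon_threshold`` of the shorter exon.
    """
    if a.chromosome != b.chromosome or a.strand != b.strand:
        return False
    ov = interval_overlap(a.span, b.span)
    if ov < span_threshold * _span_denominator(a, b, denominator):
        return False
    for ea in a.exons:
        for eb in b.exons:
            if eb[0] >= ea[1]:
                break
            x = interval_overlap(ea, eb)
            if x > exon_threshold * min(ea[1] - ea[0], eb[1] - eb[0]):
                return True
    return False


def cluster_loci(transcripts: list[TranscriptModel],
                 span_threshold: float = 0.20,
                 exon_threshold: float = 0.20,
                 denominator: str = "shorter") -> list[Locus]:
    """Partition transcripts into loci (connected components of the link).

    Every transcript lands in exactly one locus; loci are numbered in
    (chromosome, strand, start) order.
    """
    parent = list(range(len(transcripts)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    groups: dict[tuple[str, str], list[int]] = {}
    for i, t in enumerate(transcripts):
        groups.setdefault((t.chromosome, t.strand), []).append(i)

    for idxs in groups.values():
        idxs = sorted(idxs, key=lambda i: transcripts[i].span)
        for pos, j in enumerate(idxs):
            tj = transcripts[j]
            for i in idxs[:pos]:
                ti = transcripts[i]
                if transcripts_linked(ti, tj, span_threshold, exon_threshold,
                                      denominator):
                    parent[find(i)] = find(j)

    comps: dict[int, list[TranscriptModel]] = {}
    for i, t in enumerate(transcripts):
        comps.setdefault(find(i), []).append(t)
    members = sorted(comps.values(),
                     key=lambda ts: (ts[0].chromosome, ts[0].strand,
                                     min(t.span[0] for t in ts)))
    return [Locus(f"locus_{k + 1:05d}", ts[0].chromosome, ts[0].strand, ts)
            for k, ts in enumerate(members)]


# -------------------------------------------------------------- collapse

def _support_size(t: TranscriptModel) -> int:
    return len(t.support) if t.support else 1


def collapse_isoforms(locus: Locus) -> list[IsoformRecord]:
    """De-redundancy within one locus.

    Multi-exon transcripts with identical splice sites (identical intron
    chains) reduce to the one of maximal spliced length; the removed
    shorter copies fold into its support.  Mono-exon transcripts merge
    when one interval contains the other.  Idempotent, and support is
    conserved: the support counts of the output sum to the number of
    supporting reads (or transcripts) that came in.
    """
    if not locus.transcripts:
        raise ValueError("empty locus")
    multi = [t for t in locus.transcripts if t.is_multi_exon]
    mono = [t for t in locus.transcripts if not t.is_multi_exon]

    records: list[IsoformRecord] = []
    by_chain: dict[tuple, list[TranscriptModel]] = {}
    for t in multi:
        by_chain.setdefault(t.intron_chain, []).append(t)
    for chain in sorted(by_chain):
        members = by_chain[chain]
        rep = max(members, key=lambda t: (t.spliced_length, t.transcript_id))
        records.append(_make_record(rep, members))

    for t in sorted(mono, key=lambda t: (-(t.spliced_length), t.span, t.transcript_id)):
        host = next((r for r in records if not r.is_multi_exon
                     and r.representative.exons[0][0] <= t.exons[0][0]
                     and t.exons[0][1] <= r.representative.exons[0][1]), None)
        if host is None:
            records.append(_make_record(t, [t]))
        else:
            pids = [p for _, p in t.support]
            host.support_count += _support_size(t)
            host.max_support_pid = max(host.max_support_pid,
                                       max(pids) if pids else 0.0)
            host.representative.support.extend(t.support)

    for k, r in enumerate(records):
        r.isoform_id = f"{locus.locus_id}.iso{k + 1}"
    return records


def _make_record(rep: TranscriptModel, members: list[TranscriptModel]) -> IsoformRecord:
    support = [s for m in members for s in m.support]
    rep_model = TranscriptModel(rep.transcript_id, rep.chromosome, rep.strand,
                                list(rep.exons), gene_id=rep.gene_id,
                                support=support)
    pids = [p for _, p in support]
    return IsoformRecord(
        isoform_id=rep.transcript_id,
        representative=rep_model,
        support_count=sum(_support_size(m) for m in members),
        max_support_pid=max(pids) if pids else 0.0)


# ----------------------------------------------------------- full length

def flag_full_length(isoform: IsoformRecord,
                     reference: list[TranscriptModel]) -> bool:
    """True iff the isoform's intron chain includes the first splice donor
    (the donor nearest the transcript 5' end, strand-aware) of any
    overlapping same-strand reference isoform."""
    if not isoform.is_multi_exon:
        raise ValueError("full-length flag is undefined for mono-exon isoforms")
    rep = isoform.representative
    donors = set(rep.donor_sites())
    for ref in reference:
        if (ref.chromosome != rep.chromosome or ref.strand != rep.strand
                or not ref.is_multi_exon):
            continue
        if interval_overlap(ref.span, rep.span) <= 0:
            continue
        if ref.first_donor_site() in donors:
            isoform.full_length = True
            return True
    isoform.full_length = False
    return False


# -------------------------------------------------------------- novelty

def reference_gene_spans(reference: list[TranscriptModel]
                         ) -> dict[str, tuple[str, str, Interval]]:
    """gene_id -> (chromosome, strand, union span) over its transcripts."""
    spans: dict[str, tuple[str, str, int, int]] = {}
    for t in reference:
        gid = t.gene_id or t.transcript_id
        s, e = t.span
        if gid in spans:
            c, st, s0, e0 = spans[gid]
            spans[gid] = (c, st, min(s0, s), max(e0, e))
        else:
            spans[gid] = (t.chromosome, t.strand, s, e)
    return {g: (c, st, (s, e)) for g, (c, st, s, e) in spans.items()}


def classify_gene_novelty(locus: Locus, reference: list[TranscriptModel],
                          min_overlap: float = 0.20
                          ) -> tuple[str, tuple[str, ...]]:
    """Novel vs known call for a locus against reference gene spans.

    Novel when the locus has no reference overlap at all, when its best
    same-strand overlap is under ``min_overlap`` of the locus span, or
    when only opposite-strand genes reach that overlap.
    """
    span, length = locus.span, locus.span_length
    matched = []
    for gid, (chrom, strand, gspan) in reference_gene_spans(reference).items():
        if chrom != locus.chromosome or strand != locus.strand:
            continue
        if interval_overlap(span, gspan) >= min_overlap * length:
            matched.append(gid)
    locus.novelty = "known" if matched else "novel"
    locus.matched_gene_ids = tuple(sorted(matched))
    return locus.novelty, locus.matched_gene_ids


def reference_splice_sites(reference: list[TranscriptModel]
                           ) -> dict[tuple[str, str], set[tuple[str, int]]]:
    sites: dict[tuple[str, str], set[tuple[str, int]]] = {}
    for t in reference:
        sites.setdefault((t.chromosome, t.strand), set()).update(t.splice_sites())
    return sites


def classify_isoform_novelty(isoform: IsoformRecord,
                             reference: list[TranscriptModel],
                             site_window: int = 0,
                             min_support: int = 2,
                             min_single_read_pid: float = 99.0) -> str:
    """known / novel / discarded call for one collapsed isoform.

    Known requires every splice site to match a reference site (exactly,
    or within ``site_window`` bases when a fuzz window is configured);
    for mono-exon isoforms it requires coordinate identity with an
    annotated mono-exon transcript.  A candidate novel isoform is kept
    only with at least ``min_support`` supporting FLNCs, or a single FLNC
    whose local PID exceeds ``min_single_read_pid``.
    """
    rep = isoform.representative
    if rep.is_multi_exon:
        ref_sites = reference_splice_sites(reference).get(
            (rep.chromosome, rep.strand), set())
        if site_window == 0:
            known = rep.splice_sites() <= ref_sites
        else:
            by_kind: dict[str, np.ndarray] = {}
            for kind in ("D", "A"):
                by_kind[kind] = np.sort([p for k, p in ref_sites if k == kind])
            known = all(
                by_kind[k].size > 0
                and np.min(np.abs(by_kind[k] - p)) <= site_window
                for k, p in rep.splice_sites())
    else:
        exon = rep.exons[0]
        known = any(
            not r.is_multi_exon and r.chromosome == rep.chromosome
            and r.strand == rep.strand
            and abs(r.exons[0][0] - exon[0]) <= site_window
            and abs(r.exons[0][1] - exon[1]) <= site_window
            for r in reference)
    if known:
        isoform.novelty = "known"
    elif (isoform.support_count >= min_support
          or (isoform.support_count == 1
              and isoform.max_support_pid > min_single_read_pid)):
        isoform.novelty = "novel"
    else:
        isoform.novelty = "discarded"
    return isoform.novelty


# -------------------------------------------------------------- summary

LENGTH_BINS = ["<1K", "1-2K", "2-3K", ">=3K"]


def locus_length(locus: Locus, isoforms: list[IsoformRecord] | None = None,
                 statistic: str = "spliced_longest") -> int:
    """Length statistic used for binning: longest member's spliced length
    (default) or the genomic span."""
    if statistic == "span":
        return locus.span_length
    if statistic == "spliced_longest":
        models = ([r.representative for r in isoforms] if isoforms
                  else locus.transcripts)
        return max(t.spliced_length for t in models)
    raise ValueError(f"unknown statistic {statistic!r}")


def locus_length_summary(lengths: list[int] | np.ndarray) -> pd.DataFrame:
    """Bin locus lengths into <1K / 1–2K / 2–3K / >=3K with percentages."""
    lengths = np.asarray(lengths)
    edges = [-np.inf, 1000, 2000, 3000, np.inf]
    counts = [int(((lengths >= lo) & (lengths < hi)).sum())
              for lo, hi in zip(edges, edges[1:])]
    total = int(lengths.size)
    pct = [round(100.0 * c / total, 2) if total else 0.0 for c in counts]
    return pd.DataFrame({"bin": LENGTH_BINS, "count": counts, "pct": pct})


# ------------------------------------------------------------- pipeline

@dataclass
class Catalogue:
    """Full cataloguing result: loci with their collapsed isoforms."""
    loci: list[Locus]
    isoforms: dict[str, list[IsoformRecord]]  # locus_id -> kept isoforms
    discarded: int = 0

    def all_isoforms(self) -> list[IsoformRecord]:
        return [r for rs in self.isoforms.values() for r in rs]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for locus in self.loci:
            for r in self.isoforms[locus.locus_id]:
                rows.append({
                    "locus_id": locus.locus_id,
                    "isoform_id": r.isoform_id,
                    "chromosome": locus.chromosome, "strand": locus.strand,
                    "n_exons": len(r.representative.exons),
                    "spliced_length": r.representative.spliced_length,
                    "support_count": r.support_count,
                    "max_support_pid": r.max_support_pid,
                    "full_length": r.full_length,
                    "locus_novelty": locus.novelty,
                    "isoform_novelty": r.novelty})
        return pd.DataFrame(rows)


def build_catalogue(transcripts: list[TranscriptModel],
                    reference: list[TranscriptModel] | None = None,
                    **cluster_kwargs) -> Catalogue:
    """Cluster, collapse, and (when a reference is given) call novelty.

    Low-support novel candidates are discarded before any summary; novel
    loci are renamed ``NOVELG_#####``.
    """
    loci = cluster_loci(transcripts, **cluster_kwargs)
    isoforms: dict[str, list[IsoformRecord]] = {}
    discarded = 0
    novel_counter = 0
    for locus in loci:
        records = collapse_isoforms(locus)
        if reference is not None:
            classify_gene_novelty(locus, reference)
            kept = []
            for r in records:
                if classify_isoform_novelty(r, reference) == "discarded":
                    discarded += 1
                else:
                    kept.append(r)
                if r.is_multi_exon:
                    flag_full_length(r, reference)
            records = kept
            if locus.novelty == "novel":
                novel_counter += 1
                locus.locus_id = f"NOVELG_{novel_counter:05d}"
                for k, r in enumerate(records):
                    r.isoform_id = f"{locus.locus_id}.iso{k + 1}"
        isoforms[locus.locus_id] = records
    return Catalogue(loci, isoforms, discarded)
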