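"""Alternative splicing, alternative polyadenylation and fusion calling.

AS events are structural differences between isoform pairs of one locus:

* ES — a cassette exon present in one intron chain and spliced out by a
  single intron of the other that runs donor-to-acceptor across it;
* AA — two introns sharing a donor but ending at different acceptors;
* AD — two introns sharing an acceptor but starting at different donors;
* IR — an intron of one chain retained inside an exon of the other.

Donor/acceptor identity is strand-aware.  Acceptor (donor) shifts that
are fully explained by a cassette-exon skip are not double-counted as
AA/AD.  Events are de-duplicated by (type, coordinates) across pairs;
per-pair tallies are also available.

APA sites are clustered FLNC 3'-end positions; a site needs at least two
supporting reads, and a locus with two or more surviving sites is an APA
locus.  Fusion candidates are reads split between two distinct loci.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .models import Interval, IsoformRecord, TranscriptModel

AS_TYPES = ("ES", "AA", "AD", "IR")


@dataclass(frozen=True)
class ASEvent:
    locus_id: str
    type: str                    # ES | AA | AD | IR
    coordinates: tuple[int, ...]
    isoform_pair: tuple[str, str]


@dataclass
class APASite:
    locus_id: str
    position: int                # genomic 3'-end coordinate
    support: int


@dataclass
class FusionCandidate:
    read_id: str
    partner_5prime: str
    partner_3prime: str
    breakpoints: tuple[int, int]  # read coordinates of the junction


# ------------------------------------------------------------------- AS

def _donor(intron: Interval, strand: str) -> int:
    return intron[0] if strand == "+" else intron[1]


def _acceptor(intron: Interval, strand: str) -> int:
    return intron[1] if strand == "+" else intron[0]


def _pair_events(a: TranscriptModel, b: TranscriptModel) -> list[tuple[str, tuple[int, ...]]]:
    """All ES/AA/AD/IR differences between two intron chains (symmetric)."""
    strand = a.strand
    out: list[tuple[str, tuple[int, ...]]] = []
    skip_pairs: set[tuple[Interval, Interval]] = set()

    for x, y in ((a, b), (b, a)):
        cx, cy = x.intron_chain, y.intron_chain
        # ES: one intron of y spans a consecutive run of x's introns,
        # skipping the exon(s) between them.
        for iy in cy:
            for j, ix in enumerate(cx):
                if ix[0] != iy[0]:
                    continue
                for m in range(j + 1, len(cx)):
                    if cx[m][1] == iy[1]:
                        for k in range(j, m):
                            exon = (cx[k][1], cx[k + 1][0])
                            out.append(("ES", exon))
                        skip_pairs.update({(ix, iy), (iy, ix),
                                           (cx[m], iy), (iy, cx[m])})
                        break
        # IR: an intron of x contained within an exon of y.
        ys = set(cy)
        for ix in cx:
            if ix in ys:
                continue
            for ey in y.exons:
                if ey[0] <= ix[0] and ix[1] <= ey[1]:
                    out.append(("IR", ix))
                    break

    # AA / AD over cross-chain intron pairs not explained by an ES skip.
    for ia in a.intron_chain:
        for ib in b.intron_chain:
            if ia == ib or (ia, ib) in skip_pairs:
                continue
            da, db = _donor(ia, strand), _donor(ib, strand)
            xa, xb = _acceptor(ia, strand), _acceptor(ib, strand)
            if da == db and xa != xb:
                out.append(("AA", (da,) + tuple(sorted((xa, xb)))))
            elif xa == xb and da != db:
                out.append(("AD", (xa,) + tuple(sorted((da, db)))))
    return out


def enumerate_as_events(isoforms: list[IsoformRecord] | list[TranscriptModel],
                        locus_id: str = "",
                        deduplicate: bool = True) -> list[ASEvent]:
    """Pairwise AS events among the isoforms of one locus.

    With ``deduplicate`` (default) events are unique by (type,
    coordinates); the recorded pair is the first that exhibits each
    event.  Returns an empty list for fewer than two isoforms.
    """
    models = [r.representative if isinstance(r, IsoformRecord) else r
              for r in isoforms]
    names = [r.isoform_id if isinstance(r, IsoformRecord) else r.transcript_id
             for r in isoforms]
    events: list[ASEvent] = []
    seen: set[tuple[str, tuple[int, ...]]] = set()
    for i in range(len(models)):
        for j in range(i + 1, len(models)):
            pair = tuple(sorted((names[i], names[j])))
            for etype, coords in _pair_events(models[i], models[j]):
                key = (etype, coords)
                if deduplicate:
                    if key in seen:
                        continue
                    seen.add(key)
                events.append(ASEvent(locus_id, etype, coords, pair))
    return events


def as_summary(events: list[ASEvent]) -> tuple[dict[str, int], float | None]:
    """Per-type counts and the IR fraction (None when there are no events)."""
    counts = Counter(e.type for e in events)
    full = {t: counts.get(t, 0) for t in AS_TYPES}
    total = sum(full.values())
    return full, (full["IR"] / total if total else None)


# ------------------------------------------------------------------ APA

def detect_apa(three_prime_ends: list[tuple[str, int]] | list[int],
               locus_id: str = "", window: int = 20,
               min_support: int = 2) -> tuple[list[APASite], bool]:
    """Cluster FLNC 3'-end positions into polyadenylation sites.

    Positions whose consecutive gaps are within ``window`` bases join one
    cluster; a cluster's site is its support-weighted mode (smallest on
    ties) and clusters under ``min_support`` reads are dropped.  Returns
    the retained sites and whether the locus qualifies as an APA locus
    (two or more retained sites).  Output is independent of input order.
    """
    positions = sorted(p if isinstance(p, (int, np.integer)) else p[1]
                       for p in three_prime_ends)
    sites: list[APASite] = []
    cluster: list[int] = []

    def flush() -> None:
        if len(cluster) >= min_support:
            mode = Counter(cluster).most_common()
            best = min(p for p, c in mode if c == mode[0][1])
            sites.append(APASite(locus_id, best, len(cluster)))

    for p in positions:
        if cluster and p - cluster[-1] > window:
            flush()
            cluster = []
        cluster.append(p)
    if cluster:
        flush()
    return sites, len(sites) >= 2


# --------------------------------------------------------------- fusion

@dataclass
class SplitSegment:
    """One aligned fragment of a read, in read and locus coordinates."""
    read_start: int
    read_end: int
    locus_id: str


def detect_fusion(read_id: str, segments: list[SplitSegment], read_length: int,
                  min_segment_fraction: float = 0.10,
                  min_combined_coverage: float = 0.90) -> FusionCandidate | None:
    """Call a fusion candidate from a read's split placements.

    Requires two non-overlapping segments, each at least
    ``min_segment_fraction`` of the read, on two distinct loci, jointly
    covering at least ``min_combined_coverage`` of the read.  Partners
    are ordered 5'→3' by read coordinate.
    """
    if len(segments) < 2 or read_length <= 0:
        return None
    segs = sorted(segments, key=lambda s: s.read_start)
    for i in range(len(segs)):
        for j in range(i + 1, len(segs)):
            s1, s2 = segs[i], segs[j]
            if s1.locus_id == s2.locus_id:
                continue
            if s2.read_start < s1.read_end:  # overlapping in read coords
                continue
            l1, l2 = s1.read_end - s1.read_start, s2.read_end - s2.read_start
            if min(l1, l2) < min_segment_fraction * read_length:
                continue
            if l1 + l2 < min_combined_coverage * read_length:
                continue
            return FusionCandidate(read_id, s1.locus_id, s2.locus_id,
                                   (s1.read_end, s2.read_start))
    return None


def detect_fusions(reads: dict[str, tuple[int, list[SplitSegment]]],
                   **kwargs) -> list[FusionCandidate]:
    """Fusion candidates over a read set of (read_length, segments)."""
    out = []
    for rid in sorted(reads):
        length, segs = reads[rid]
        cand = detect_fusion(rid, segs, length, **kwargs)
        if cand is not None:
            out.append(cand)
    return out


def events_frame(events: list[ASEvent]) -> pd.DataFrame:
    return pd.DataFrame([{
        "locus_id": e.locus_id, "type": e.type,
        "coordinates": ",".join(map(str, np.atleast_1d(e.coordinates))),
        "isoform_1": e.isoform_pair[0], "isoform_2": e.isoform_pair[1]}
        for e in events])
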