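"""Alignment quality triage for FLNC-to-genome placements.

Percent identity comes in two flavors: local (matches over aligned
columns) and global (matches over the full read length).  Each read is
placed in one of four categories — unmapped, multiple-best, low PID, high
quality — and two alignment rounds (before and after hybrid error
correction) are merged read-by-read, keeping the better outcome.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import Interval, TranscriptModel, interval_overlap

CATEGORY_RANK = {"unmapped": 0, "multiple_best": 1, "low_pid": 2, "high_quality": 3}


@dataclass
class AlignmentRecord:
    """One read-to-genome placement with its identity statistics."""

    read_id: str
    chromosome: str
    strand: str
    blocks: list[Interval]
    matches: int
    aligned_columns: int
    read_length: int
    gaps: int = 0
    global_pid: float | None = None
    local_pid: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        self.blocks = sorted(tuple(b) for b in self.blocks)
        for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:]):
            if s2 < e1:
                raise ValueError("alignment blocks overlap")

    @property
    def score(self) -> float:
        """Matches minus mismatches minus gaps — the tie-break currency."""
        return self.matches - (self.aligned_columns - self.matches) - self.gaps


def compute_pid(aln: AlignmentRecord) -> tuple[float, float]:
    """(global, local) percent identity of one placement.

    local = 100·matches/aligned_columns; global = 100·matches/read_length.
    Global can never exceed local because a read is at least as long as
    its aligned portion.
    """
    if aln.aligned_columns <= 0:
        raise ValueError("aligned_columns must be positive for a mapped read")
    if aln.matches > aln.aligned_columns:
        raise ValueError("matches cannot exceed aligned columns")
    if aln.matches > aln.read_length:
        raise ValueError("matches cannot exceed read length")
    aln.local_pid = 100.0 * aln.matches / aln.aligned_columns
    aln.global_pid = 100.0 * aln.matches / aln.read_length
    return aln.global_pid, aln.local_pid


def classify_alignments(placements: list[AlignmentRecord],
                        pid_threshold: float = 90.0,
                        score_tie_fraction: float = 0.01
                        ) -> tuple[str, AlignmentRecord | None]:
    """Category of one read given all its placements.

    No placement → unmapped; two or more placements whose scores agree
    within ``score_tie_fraction`` of the best → multiple-best; a unique
    best with local PID under the threshold → low PID; otherwise high
    quality.  Returns the category and the best placement (None when
    unmapped).
    """
    if not 0.0 < pid_threshold < 100.0:
        raise ValueError("pid_threshold must lie in (0, 100)")
    if not placements:
        return "unmapped", None
    for a in placements:
        if a.local_pid is None:
            compute_pid(a)
    best = max(placements, key=lambda a: (a.score, a.local_pid))
    ties = [a for a in placements
            if a is not best and abs(best.score - a.score) <= score_tie_fraction * abs(best.score)]
    if ties:
        cat = "multiple_best"
    elif best.local_pid < pid_threshold:
        cat = "low_pid"
    else:
        cat = "high_quality"
    best.category = cat
    return cat, best


def classify_all(alignments: list[AlignmentRecord], read_ids: list[str] | None = None,
                 pid_threshold: float = 90.0) -> dict[str, tuple[str, AlignmentRecord | None]]:
    """Per-read classification over a flat alignment list.

    ``read_ids`` names the full read universe; reads without any
    placement come out unmapped.
    """
    by_read: dict[str, list[AlignmentRecord]] = {}
    for a in alignments:
        by_read.setdefault(a.read_id, []).append(a)
    universe = read_ids if read_ids is not None else sorted(by_read)
    return {rid: classify_alignments(by_read.get(rid, []), pid_threshold)
            for rid in universe}


def merge_rounds(pre: dict[str, tuple[str, AlignmentRecord | None]],
                 post: dict[str, tuple[str, AlignmentRecord | None]]
                 ) -> dict[str, tuple[str, AlignmentRecord | None]]:
    """Combine pre- and post-correction rounds, keeping the better round.

    Ranking: high quality > low PID > multiple-best > unmapped; ties go
    to the round with the higher local PID.  A read absent from one round
    counts as unmapped there, so merging can only improve a read's
    category.
    """
    merged = {}
    for rid in sorted(set(pre) | set(post)):
        a = pre.get(rid, ("unmapped", None))
        b = post.get(rid, ("unmapped", None))
        ka = (CATEGORY_RANK[a[0]], a[1].local_pid if a[1] is not None else -1.0)
        kb = (CATEGORY_RANK[b[0]], b[1].local_pid if b[1] is not None else -1.0)
        merged[rid] = a if ka >= kb else b
    return merged


def category_table(rounds: dict[str, dict[str, tuple[str, AlignmentRecord | None]]]
                   ) -> pd.DataFrame:
    """Counts and percentages per category for each round (plus merge)."""
    order = ["unmapped", "multiple_best", "low_pid", "high_quality"]
    out = {}
    for name, result in rounds.items():
        counts = pd.Series([c for c, _ in result.values()]).value_counts()
        col = {}
        total = len(result)
        for cat in order:
            n = int(counts.get(cat, 0))
            col[cat] = n
            col[f"{cat}_pct"] = round(100.0 * n / total, 2) if total else 0.0
        out[name] = col
    return pd.DataFrame(out)


def exon_coverage(alignments: list[AlignmentRecord],
                  annotation: list[TranscriptModel]
                  ) -> tuple[pd.DataFrame, pd.Series]:
    """Per-exon read coverage percentage plus a decile histogram.

    Coverage of an exon is the percentage of its bases under at least one
    aligned block on the same chromosome.  The histogram bins are
    [0,10), [10,20), …, [80,90), [90,100].
    """
    if not annotation:
        raise ValueError("annotation must be non-empty")
    blocks_by_chrom: dict[str, list[Interval]] = {}
    for a in alignments:
        blocks_by_chrom.setdefault(a.chromosome, []).extend(a.blocks)
    merged_by_chrom = {c: _merge_intervals(v) for c, v in blocks_by_chrom.items()}

    rows = []
    for t in annotation:
        merged = merged_by_chrom.get(t.chromosome, [])
        starts = [s for s, _ in merged]
        for i, (es, ee) in enumerate(t.exons):
            covered = 0
            j = np.searchsorted(starts, es, side="right") - 1
            j = max(j, 0)
            while j < len(merged) and merged[j][0] < ee:
                covered += interval_overlap((es, ee), merged[j])
                j += 1
            rows.append({"transcript_id": t.transcript_id, "exon_index": i,
                         "start": es, "end": ee,
                         "coverage_pct": 100.0 * covered / (ee - es)})
    df = pd.DataFrame(rows)
    edges = list(range(0, 100, 10)) + [100.0001]
    labels = [f"[{a},{a + 10})" for a in range(0, 80, 10)] + ["[80,90)", "[90,100]"]
    hist = pd.cut(df["coverage_pct"], bins=edges, labels=labels,
                  right=False, include_lowest=True).value_counts().sort_index()
    return df, hist


def _merge_intervals(ivs: list[Interval]) -> list[Interval]:
    if not ivs:
        return []
    ivs = sorted(ivs)
    out = [list(ivs[0])]
    for s, e in ivs[1:]:
        if s <= out[-1][1]:
            out[-1][1] = max(out[-1][1], e)
        else:
            out.append([s, e])
    return [tuple(x) for x in out]
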