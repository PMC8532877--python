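"""Core genomic feature containers shared across the pipeline.

Coordinates are 0-based half-open throughout the library; GTF output is
converted to 1-based inclusive at the I/O boundary and BED12 stays 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property


Interval = tuple[int, int]


def interval_overlap(a: Interval, b: Interval) -> int:
    """Length of the intersection of two half-open intervals (0 if disjoint)."""
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


@dataclass
class TranscriptModel:
    """A stranded exon chain on one chromosome.

    The atom of loci clustering, isoform collapse and splicing-event
    analysis.  ``support`` carries the FLNC read ids (with their local
    percent identity) that back this model.
    """

    transcript_id: str
    chromosome: str
    strand: str  # '+' or '-'
    exons: list[Interval]
    gene_id: str | None = None
    support: list[tuple[str, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        exons = sorted(tuple(e) for e in self.exons)
        for (s, e) in exons:
            if e <= s:
                raise ValueError(f"zero/negative-length exon ({s}, {e})")
        for (_, e1), (s2, _) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValueError("exons overlap within one transcript")
        self.exons = exons

    @property
    def span(self) -> Interval:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def span_length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def introns(self) -> tuple[Interval, ...]:
        return tuple(
            (e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])
        )

    @property
    def intron_chain(self) -> tuple[Interval, ...]:
        """Ordered intron coordinates; identity of chains defines redundancy."""
        return self.introns

    @property
    def is_multi_exon(self) -> bool:
        return len(self.exons) > 1

    def donor_sites(self) -> tuple[int, ...]:
        """Genomic coordinates of splice donors (intron 5' boundaries)."""
        if self.strand == "+":
            return tuple(s for s, _ in self.introns)
        return tuple(e for _, e in self.introns)

    def acceptor_sites(self) -> tuple[int, ...]:
        if self.strand == "+":
            return tuple(e for _, e in self.introns)
        return tuple(s for s, _ in self.introns)

    def splice_sites(self) -> frozenset[tuple[str, int]]:
        """Strand-aware splice sites as ('D'|'A', coordinate) pairs."""
        return frozenset(
            [("D", p) for p in self.donor_sites()]
            + [("A", p) for p in self.acceptor_sites()]
        )

    def first_donor_site(self) -> int | None:
        """The splice donor nearest the transcript 5' end (None if mono-exon)."""
        donors = self.donor_sites()
        if not donors:
            return None
        return min(donors) if self.strand == "+" else max(donors)

    def three_prime_end(self) -> int:
        """Genomic coordinate of the transcript 3' terminus."""
        return self.span[1] if self.strand == "+" else self.span[0]

    def spliced_sequence(self, genome: dict[str, str | bytearray]) -> str:
        """Transcript-strand sequence spliced from a genome dict."""
        chrom = genome[self.chromosome]
        seq = "".join(
            chrom[s:e].decode() if isinstance(chrom, (bytes, bytearray)) else chrom[s:e]
            for s, e in self.exons
        )
        return revcomp(seq) if self.strand == "-" else seq

    def project_to_genome(self, t_start: int, t_end: int) -> list[Interval]:
        """Map a transcript-coordinate interval to genomic exon blocks.

        Transcript coordinates run 5'→3' on the transcript strand.
        """
        if not (0 <= t_start < t_end <= self.spliced_length):
            raise ValueError("transcript interval out of bounds")
        exons = self.exons if self.strand == "+" else self.exons[::-1]
        blocks: list[Interval] = []
        offset = 0
        for s, e in exons:
            ln = e - s
            lo, hi = max(t_start - offset, 0), min(t_end - offset, ln)
            if lo < hi:
                if self.strand == "+":
                    blocks.append((s + lo, s + hi))
                else:
                    blocks.append((e - hi, e - lo))
            offset += ln
        return sorted(blocks)


_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Locus:
    """A strand-specific cluster of overlapping transcript models."""

    locus_id: str
    chromosome: str
    strand: str
    transcripts: list[TranscriptModel]
    novelty: str | None = None  # 'known' | 'novel'
    matched_gene_ids: tuple[str, ...] = ()

    @property
    def span(self) -> Interval:
        return (
            min(t.span[0] for t in self.transcripts),
            max(t.span[1] for t in self.transcripts),
        )

    @property
    def span_length(self) -> int:
        s, e = self.span
        return e - s


@dataclass
class IsoformRecord:
    """A de-redundant isoform: one intron chain with its representative model."""

    isoform_id: str
    representative: TranscriptModel
    support_count: int
    max_support_pid: float
    full_length: bool | None = None
    novelty: str | None = None  # 'known' | 'novel' | 'discarded'

    @property
    def intron_chain(self) -> tuple[Interval, ...]:
        return self.representative.intron_chain

    @property
    def is_multi_exon(self) -> bool:
        return self.representative.is_multi_exon
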