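"""CCS-level long-read classification and short-read QC filters.

Long reads are triaged into the categories a full-length transcriptome
run reports per size library: filtered short (outside the length window),
non-full-length (missing a primer or the polyA tail), full-length (both
primers plus polyA) and FLNC (full-length with no internal primer copy,
i.e. non-chimeric).  The three top-level categories partition the input;
FLNC is the non-concatemer subset of full-length.

Short-read QC applies the standard pre-alignment filters: adaptor
contamination, excess unknown bases, excess low-quality bases.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import revcomp
from .simdata import DEFAULT_PRIMER3, DEFAULT_PRIMER5


@dataclass
class PrimerConfig:
    """Primer/polyA detection settings and the CCS length window."""

    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    max_mismatches: int = 2
    polya_min_length: int = 20
    polya_min_purity: float = 0.9
    min_read_length: int = 50
    max_read_length: int = 15_000

    def __post_init__(self) -> None:
        if self.min_read_length >= self.max_read_length:
            raise ValueError("min_read_length must be < max_read_length")
        if not 0.0 < self.polya_min_purity <= 1.0:
            raise ValueError("polya_min_purity must lie in (0, 1]")
        if len(self.primer5) < 8 or len(self.primer3) < 8:
            raise ValueError("primers must be at least 8 nt")


@dataclass
class ReadRecord:
    """One CCS read with its detection flags and classification state."""

    read_id: str
    sequence: str
    has_primer5: bool | None = None
    has_primer3: bool | None = None
    has_polya: bool | None = None
    internal_primer_hits: int | None = None
    category: str | None = None
    primer3_pos: int | None = field(default=None, repr=False)

    @property
    def length(self) -> int:
        return len(self.sequence)


def _hamming_scan(seq: str, pattern: str, max_mm: int) -> np.ndarray:
    """Start positions where `pattern` matches `seq` with <= max_mm mismatches."""
    n, m = len(seq), len(pattern)
    if n < m:
        return np.empty(0, dtype=np.int64)
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(s, m)
    mism = (windows != p).sum(axis=1)
    return np.nonzero(mism <= max_mm)[0]


def detect_primers(sequence: str, primers: PrimerConfig
                   ) -> tuple[bool, bool, int, int | None]:
    """Locate the 5' primer, the (reverse-complemented) 3' primer and any
    internal primer copies.

    Terminal windows of twice the primer length at each read end are
    scanned with a Hamming-distance matcher; matches outside both windows
    count as internal hits (concatemer evidence).  Returns
    ``(has_primer5, has_primer3, internal_hits, primer3_start)`` where the
    last element is the leftmost 3'-primer match inside the 3' window, for
    downstream polyA localization.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    p5, p3rc = primers.primer5, revcomp(primers.primer3)
    w5 = 2 * len(p5)
    w3 = 2 * len(p3rc)
    n = len(sequence)

    hits5 = _hamming_scan(sequence, p5, primers.max_mismatches)
    hits3 = _hamming_scan(sequence, p3rc, primers.max_mismatches)
    has5 = bool(np.any(hits5 < w5))
    win3_start = max(0, n - w3)
    in3 = hits3[hits3 + len(p3rc) > win3_start]
    has3 = in3.size > 0
    p3_pos = int(in3.min()) if has3 else None

    internal = 0
    for hits, plen in ((hits5, len(p5)), (hits3, len(p3rc))):
        for h in hits:
            if h >= w5 and h + plen <= win3_start:
                internal += 1
    return has5, has3, internal, p3_pos


def detect_polya(sequence: str, primers: PrimerConfig,
                 primer3_pos: int | None = None) -> bool:
    """True iff a near-terminal A-run meets the length and purity bars.

    The tail must contain at least ``polya_min_length`` A bases inside a
    window of A-fraction >= ``polya_min_purity``, ending within 50 bases
    of the 3' primer start (or of the read end when no primer was found).
    Requiring the A *count* (not just the fraction) makes the length bar
    exact: 19 A's never satisfy a 20-base minimum, whatever the purity.
    """
    if not sequence:
        raise ValueError("empty read sequence")
    min_a = primers.polya_min_length
    wmax = int(min_a / primers.polya_min_purity)
    region_end = primer3_pos if primer3_pos is not None else len(sequence)
    lo = max(0, region_end - 50 - wmax)
    segment = sequence[lo:region_end]
    if len(segment) < min_a:
        return False
    a = np.frombuffer(segment.encode(), dtype=np.uint8) == ord("A")
    csum = np.concatenate([[0], np.cumsum(a)])
    for w in {min_a, min(wmax, len(segment))}:
        counts = csum[w:] - csum[:-w]
        if counts.size and (counts >= min_a).any():
            return True
    return False


def classify_ccs(read: ReadRecord, primers: PrimerConfig) -> str:
    """Assign the read's library category from its detection flags.

    Reads outside the length window are ``filtered_short``; otherwise
    ``full_length`` requires both primers and the polyA tail, and
    ``flnc`` additionally requires no internal primer hit.  The returned
    category is the finest one (``flnc`` implies the full-length
    criteria); tabulations treat FLNC as a subset of full-length.
    """
    if read.has_primer5 is None or read.has_primer3 is None or read.has_polya is None \
            or read.internal_primer_hits is None:
        raise ValueError(f"detection flags unset on read {read.read_id}")
    n = read.length
    if n < primers.min_read_length or n > primers.max_read_length:
        cat = "filtered_short"
    elif read.has_primer5 and read.has_primer3 and read.has_polya:
        cat = "flnc" if read.internal_primer_hits == 0 else "full_length"
    else:
        cat = "non_full_length"
    read.category = cat
    return cat


def annotate_and_classify(reads: dict[str, str],
                          primers: PrimerConfig | None = None) -> list[ReadRecord]:
    """Run primer/polyA detection then classification over a read set."""
    primers = primers or PrimerConfig()
    out = []
    for rid, seq in reads.items():
        rec = ReadRecord(rid, seq)
        rec.has_primer5, rec.has_primer3, rec.internal_primer_hits, rec.primer3_pos = \
            detect_primers(seq, primers)
        rec.has_polya = detect_polya(seq, primers, rec.primer3_pos)
        classify_ccs(rec, primers)
        out.append(rec)
    return out


def classification_summary(records: list[ReadRecord]) -> pd.DataFrame:
    """Library-style tally: CCS total, feature counts, category partition.

    5'/3'/polyA feature counts are taken over all CCS reads, before length
    filtering.  ``full_length`` includes FLNC, so filtered short +
    non-full-length + full-length equals the CCS total.
    """
    cats = Counter(r.category for r in records)
    full = cats.get("full_length", 0) + cats.get("flnc", 0)
    flnc = [r for r in records if r.category == "flnc"]
    rows = {
        "CCS": len(records),
        "5' reads": sum(r.has_primer5 for r in records),
        "3' reads": sum(r.has_primer3 for r in records),
        "Poly-A reads": sum(r.has_polya for r in records),
        "Filtered short reads": cats.get("filtered_short", 0),
        "Non-full-length reads": cats.get("non_full_length", 0),
        "Full-length reads": full,
        "FLNC reads": len(flnc),
        "Average FLNC length": round(float(np.mean([r.length for r in flnc])))
        if flnc else 0,
    }
    return pd.DataFrame({"count": rows})


def filter_short_reads(sequence: str, qualities: list[int] | np.ndarray,
                       adaptors: tuple[str, ...] = (),
                       max_n_fraction: float = 0.10,
                       quality_floor: int = 20,
                       max_low_quality_fraction: float = 0.50) -> bool:
    """Short-read QC keep/discard decision.

    Discards a read on any of: an adaptor substring match; unknown bases
    (N) over 10% of the length; bases under the Phred-20 floor over 50%
    of the length.  Both fraction tests are strict ("more than").
    """
    q = np.asarray(qualities)
    if q.size != len(sequence):
        raise ValueError("qualities length does not match sequence length")
    if any(a and a in sequence for a in adaptors):
        return False
    n_frac = sequence.upper().count("N") / len(sequence)
    if n_frac > max_n_fraction:
        return False
    if (q < quality_floor).mean() > max_low_quality_fraction:
        return False
    return True
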