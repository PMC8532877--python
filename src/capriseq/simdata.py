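"""Synthetic genome / annotation / long-read / count-matrix generator.

Emulates the study design the pipeline targets: a compact multi-isoform
genome with cassette exons, alternative donors/acceptors, retained introns
and alternative 3' ends; full-length cDNA reads carrying the 5'/3' PCR
primers and a polyA tail (with configurable truncation, sequencing error
and two-fragment chimera rates); and a two-condition negative-binomial
count matrix with a stated fraction of truly differential genes.  Every
output comes with a truth record so downstream stages can be scored
exactly.

All randomness flows from a single integer seed; identical configurations
produce byte-identical files.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .models import Interval, TranscriptModel, revcomp
from . import io as cio


class ConfigurationError(ValueError):
    """A simulation parameter is outside its valid domain."""


BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Distinct PCR primers: a SMARTer-style 5' oligo and an unrelated 3' primer.
DEFAULT_PRIMER5 = "AAGCAGTGGTATCAACGCAGAGTAC"
DEFAULT_PRIMER3 = "CGCACTCTGATATGTGGTACCTCAG"


@dataclass
class SimConfig:
    """All tunable parameters of the synthetic study.

    Defaults describe a small but structurally complete instance: two
    ~100 kb chromosomes, multi-exon genes with every splicing-event class
    represented, reads at ~1% error with modest truncation and chimera
    rates, and a 4-vs-4 count design with 10% true differential genes at
    |log2FC| = 2.
    """

    seed: int = 0
    # genome / annotation
    n_chromosomes: int = 2
    chromosome_length: int = 120_000
    n_genes: int = 20
    isoforms_per_gene: tuple[int, int] = (2, 4)    # uniform inclusive
    exon_length: tuple[int, int] = (80, 300)
    intron_length: tuple[int, int] = (60, 400)
    exons_per_gene: tuple[int, int] = (3, 8)
    as_event_rates: dict[str, float] = field(default_factory=lambda: {
        "ES": 0.35, "AA": 0.20, "AD": 0.20, "IR": 0.15, "APA": 0.20})
    # reads
    n_reads: int = 500
    read_error_rate: float = 0.01
    chimera_rate: float = 0.02
    trunc5_rate: float = 0.15
    trunc3_rate: float = 0.10
    short_read_rate: float = 0.05
    primer5: str = DEFAULT_PRIMER5
    primer3: str = DEFAULT_PRIMER3
    polya_length: int = 30
    # counts
    de_fraction: float = 0.10
    lfc_magnitude: float = 2.0
    nb_dispersion: float = 0.05
    n_samples_per_group: int = 4
    depth_range: tuple[float, float] = (0.7, 1.4)

    def __post_init__(self) -> None:
        rates = {"read_error_rate": self.read_error_rate,
                 "chimera_rate": self.chimera_rate,
                 "trunc5_rate": self.trunc5_rate,
                 "trunc3_rate": self.trunc3_rate,
                 "short_read_rate": self.short_read_rate,
                 "de_fraction": self.de_fraction,
                 **{f"as_event_rates[{k}]": v for k, v in self.as_event_rates.items()}}
        for name, r in rates.items():
            if not 0.0 <= r <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {r}")
        for name, v in [("n_chromosomes", self.n_chromosomes),
                        ("chromosome_length", self.chromosome_length),
                        ("n_genes", self.n_genes), ("n_reads", self.n_reads),
                        ("polya_length", self.polya_length)]:
            if v <= 0:
                raise ConfigurationError(f"{name} must be positive, got {v}")
        if self.nb_dispersion < 0:
            raise ConfigurationError("nb_dispersion must be non-negative")
        if not self.primer5 or not self.primer3 or self.primer5 == self.primer3:
            raise ConfigurationError("primers must be non-empty and distinct")

    def rng(self, stream: int) -> np.random.Generator:
        """A generator for one named substream, independent across streams."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class GeneTruth:
    gene_id: str
    chromosome: str
    strand: str
    isoforms: list[TranscriptModel]
    as_events: list[str]


@dataclass
class ReadSegment:
    """True placement of one read fragment (chimeras have two)."""
    transcript_id: str
    gene_id: str
    chromosome: str
    strand: str
    blocks: list[Interval]          # genomic exon blocks of the fragment
    read_span: tuple[int, int]      # fragment location in read coordinates


@dataclass
class ReadTruth:
    read_id: str
    category: str                   # full_length | non_full_length | chimeric | filtered_short
    segments: list[ReadSegment]


@dataclass
class TruthSet:
    """Ground truth for everything the generator emitted."""
    genes: dict[str, GeneTruth] = field(default_factory=dict)
    reads: dict[str, ReadTruth] = field(default_factory=dict)
    de: pd.DataFrame | None = None  # gene_id, is_de, true_log2fc (BF/LD)

    def transcripts(self) -> list[TranscriptModel]:
        return [t for g in self.genes.values() for t in g.isoforms]


# ------------------------------------------------------------------- genome

def gen_genome(config: SimConfig) -> dict[str, bytearray]:
    """Uniform-random chromosomes of the configured number and length."""
    if config.chromosome_length < 10_000:
        raise ConfigurationError("chromosome_length must be >= 10,000")
    rng = config.rng(1)
    genome: dict[str, bytearray] = {}
    for i in range(config.n_chromosomes):
        idx = rng.integers(0, 4, size=config.chromosome_length)
        genome[f"chr{i + 1}"] = bytearray(BASES[idx].tobytes())
    return genome


# --------------------------------------------------------------- annotation

_APA_MARGIN = 400


def gen_annotation(genome: dict[str, bytearray],
                   config: SimConfig) -> tuple[list[TranscriptModel], TruthSet]:
    """Place non-overlapping multi-isoform genes and write canonical introns.

    Mutates ``genome`` in place so every intron carries GT..AG boundaries on
    its transcript strand.  Additional isoforms derive from the gene's base
    exon chain by applying the configured event classes (cassette-exon
    skip, donor/acceptor shift, intron retention, alternative 3' end);
    duplicate chains are discarded, so zero event rates yield
    single-isoform genes.
    """
    rng = config.rng(2)
    chrom_names = sorted(genome)
    truth = TruthSet()
    transcripts: list[TranscriptModel] = []
    cursors = {c: 200 for c in chrom_names}
    chrom_i = 0

    for g in range(config.n_genes):
        n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        ex_lens = rng.integers(config.exon_length[0], config.exon_length[1] + 1, size=n_ex)
        in_lens = rng.integers(config.intron_length[0], config.intron_length[1] + 1,
                               size=n_ex - 1)
        footprint = int(ex_lens.sum() + in_lens.sum()) + 2 * _APA_MARGIN
        gap = int(rng.integers(500, 2000))

        placed = False
        for _ in range(len(chrom_names)):
            chrom = chrom_names[chrom_i % len(chrom_names)]
            if cursors[chrom] + footprint + gap < len(genome[chrom]):
                placed = True
                break
            chrom_i += 1
        if not placed:
            raise ConfigurationError(
                f"genome too small for {config.n_genes} genes (failed at gene {g})")

        start = cursors[chrom] + _APA_MARGIN
        cursors[chrom] = start + footprint + gap - _APA_MARGIN
        chrom_i += 1
        strand = "+" if rng.random() < 0.5 else "-"
        gene_id = f"simG{g + 1:04d}"

        base_exons: list[Interval] = []
        pos = start
        for k in range(n_ex):
            base_exons.append((pos, pos + int(ex_lens[k])))
            pos += int(ex_lens[k])
            if k < n_ex - 1:
                pos += int(in_lens[k])

        isoforms = [TranscriptModel(f"{gene_id}.t1", chrom, strand,
                                    list(base_exons), gene_id=gene_id)]
        chains = {(tuple(base_exons))}
        events: list[str] = []
        n_iso = int(rng.integers(config.isoforms_per_gene[0],
                                 config.isoforms_per_gene[1] + 1))
        for _k in range(1, n_iso):
            for _try in range(10):
                exons, applied = _derive_isoform(base_exons, strand, config, rng)
                key = tuple(exons)
                if applied and key not in chains:
                    chains.add(key)
                    isoforms.append(TranscriptModel(
                        f"{gene_id}.t{len(isoforms) + 1}", chrom, strand,
                        exons, gene_id=gene_id))
                    events.extend(applied)
                    break

        for t in isoforms:
            _write_canonical_introns(genome[chrom], t)
        truth.genes[gene_id] = GeneTruth(gene_id, chrom, strand, isoforms, events)
        transcripts.extend(isoforms)

    return transcripts, truth


def _derive_isoform(base: list[Interval], strand: str, config: SimConfig,
                    rng: np.random.Generator) -> tuple[list[Interval], list[str]]:
    """Apply the configured event classes to a copy of the base exon chain."""
    exons = [list(e) for e in base]
    applied: list[str] = []
    rates = config.as_event_rates

    if len(exons) >= 3 and rng.random() < rates.get("ES", 0.0):
        del exons[int(rng.integers(1, len(exons) - 1))]
        applied.append("ES")
    if len(exons) >= 2 and rng.random() < rates.get("AA", 0.0):
        if _shift_boundary(exons, "acceptor", strand, rng):
            applied.append("AA")
    if len(exons) >= 2 and rng.random() < rates.get("AD", 0.0):
        if _shift_boundary(exons, "donor", strand, rng):
            applied.append("AD")
    if len(exons) >= 2 and rng.random() < rates.get("IR", 0.0):
        i = int(rng.integers(0, len(exons) - 1))
        exons[i] = [exons[i][0], exons[i + 1][1]]
        del exons[i + 1]
        applied.append("IR")
    if rng.random() < rates.get("APA", 0.0):
        d = int(rng.integers(100, 301))
        if strand == "+":
            exons[-1][1] += d
        else:
            exons[0][0] -= d
        applied.append("APA")
    return [tuple(e) for e in exons], applied


def _shift_boundary(exons: list[list[int]], site: str, strand: str,
                    rng: np.random.Generator) -> bool:
    """Move one intron boundary into its flanking exon (strand-aware).

    Returns False (no change) when the flanking exon is too small to
    absorb the shift.
    """
    i = int(rng.integers(0, len(exons) - 1))          # intron between exon i, i+1
    d = int(rng.integers(6, 31))
    genomic_end = (site == "acceptor") == (strand == "+")
    if genomic_end:                                    # move intron end rightward
        if exons[i + 1][1] - exons[i + 1][0] > d + 20:
            exons[i + 1][0] += d
            return True
    else:                                              # move intron start leftward
        if exons[i][1] - exons[i][0] > d + 20:
            exons[i][1] -= d
            return True
    return False


def _write_canonical_introns(chrom: bytearray, t: TranscriptModel) -> None:
    for s, e in t.introns:
        if t.strand == "+":
            chrom[s:s + 2] = b"GT"
            chrom[e - 2:e] = b"AG"
        else:
            chrom[s:s + 2] = b"CT"
            chrom[e - 2:e] = b"AC"


# -------------------------------------------------------------------- reads

def sim_flnc_reads(genome: dict[str, bytearray],
                   transcripts: list[TranscriptModel],
                   truth: TruthSet,
                   config: SimConfig) -> tuple[dict[str, str], list[tuple[str, TranscriptModel]], pd.DataFrame]:
    """Simulate CCS-level cDNA reads with primers, polyA and known truth.

    Returns (reads, true alignment rows for BED12, per-read label table)
    and fills ``truth.reads``.  Non-chimeric reads read
    ``primer5 + cDNA + polyA + revcomp(primer3)`` modulo the configured 5'
    and 3' truncations; chimeric reads concatenate two transcript cDNAs
    around an internal 5'-primer copy; short fragments fall below the
    minimum read length.
    """
    if config.read_error_rate >= 0.5:
        raise ConfigurationError("read_error_rate must be < 0.5")
    rng = config.rng(3)
    p5, p3rc = config.primer5, revcomp(config.primer3)
    polya = "A" * config.polya_length
    tx_seq = {t.transcript_id: t.spliced_sequence(genome) for t in transcripts}

    reads: dict[str, str] = {}
    aln_rows: list[tuple[str, TranscriptModel]] = []
    labels = []
    for i in range(config.n_reads):
        rid = f"read{i + 1:06d}"
        u = rng.random()
        if u < config.short_read_rate:
            ln = int(rng.integers(20, 46))
            seq = "".join(chr(b) for b in BASES[rng.integers(0, 4, size=ln)])
            rt = ReadTruth(rid, "filtered_short", [])
        elif u < config.short_read_rate + config.chimera_rate and len(transcripts) >= 2:
            # Keep fragment pairs roughly balanced so each fragment stays
            # >= 10% of the read and the two jointly cover >= 90% of it —
            # the shape a two-fragment concatemer artifact takes.
            overhead = 2 * len(p5) + config.polya_length + len(p3rc)
            for _try in range(100):
                i1, i2 = rng.choice(len(transcripts), size=2, replace=False)
                t1, t2 = transcripts[int(i1)], transcripts[int(i2)]
                l1 = t1.spliced_length
                l2 = t2.spliced_length
                total = l1 + l2 + overhead
                if min(l1, l2) >= 0.1 * total and (l1 + l2) >= 0.9 * total:
                    break
            c1, c2 = tx_seq[t1.transcript_id], tx_seq[t2.transcript_id]
            seq = p5 + c1 + p5 + c2 + polya + p3rc
            o1 = len(p5)
            o2 = o1 + len(c1) + len(p5)
            rt = ReadTruth(rid, "chimeric", [
                ReadSegment(t1.transcript_id, t1.gene_id, t1.chromosome, t1.strand,
                            list(t1.exons), (o1, o1 + len(c1))),
                ReadSegment(t2.transcript_id, t2.gene_id, t2.chromosome, t2.strand,
                            list(t2.exons), (o2, o2 + len(c2)))])
        else:
            t = transcripts[int(rng.integers(0, len(transcripts)))]
            full = tx_seq[t.transcript_id]
            L = len(full)
            t5 = rng.random() < config.trunc5_rate
            t3 = rng.random() < config.trunc3_rate
            cut5 = int(rng.integers(1, max(2, L // 4))) if t5 else 0
            cut3 = int(rng.integers(1, max(2, L // 4))) if t3 else 0
            cdna = full[cut5:L - cut3]
            head = "" if t5 else p5
            tail = "" if t3 else polya + p3rc
            seq = head + cdna + tail
            blocks = t.project_to_genome(cut5, L - cut3)
            cat = "full_length" if not (t5 or t3) else "non_full_length"
            rt = ReadTruth(rid, cat, [
                ReadSegment(t.transcript_id, t.gene_id, t.chromosome, t.strand,
                            blocks, (len(head), len(head) + len(cdna)))])
        if config.read_error_rate > 0:
            seq = _mutate(seq, config.read_error_rate, rng)
        reads[rid] = seq
        truth.reads[rid] = rt
        for j, seg in enumerate(rt.segments):
            name = rid if len(rt.segments) == 1 else f"{rid}/{j + 1}"
            aln_rows.append((name, TranscriptModel(name, seg.chromosome,
                                                   seg.strand, seg.blocks)))
        labels.append({
            "read_id": rid, "category": rt.category,
            "transcript_ids": ",".join(s.transcript_id for s in rt.segments),
            "gene_ids": ",".join(s.gene_id for s in rt.segments),
            "length": len(seq)})
    return reads, aln_rows, pd.DataFrame(labels)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Substitutions (80%), deletions (10%) and insertions (10%) at `rate`."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    hit = rng.random(arr.size) < rate
    if not hit.any():
        return seq
    kinds = rng.random(arr.size)
    out = []
    for i, b in enumerate(arr):
        if not hit[i]:
            out.append(chr(b))
        elif kinds[i] < 0.8:  # substitution to a different base
            out.append(chr(BASES[(np.searchsorted(BASES, b) + int(rng.integers(1, 4))) % 4]))
        elif kinds[i] < 0.9:  # deletion
            pass
        else:                 # insertion before the base
            out.append(chr(BASES[int(rng.integers(0, 4))]) + chr(b))
    return "".join(out)


# ------------------------------------------------------------------- counts

@dataclass
class CountSim:
    """Simulated count matrix with its ground truth."""

    counts: pd.DataFrame        # genes × samples
    lengths: pd.Series          # per-gene effective length, bases
    groups: pd.Series           # sample -> 'LD' | 'BF'
    truth: pd.DataFrame         # gene_id-indexed: is_de, true_log2fc (BF/LD)
    depth: pd.Series            # true per-sample depth multipliers

    def __iter__(self):
        return iter((self.counts, self.lengths, self.groups, self.truth))


def sim_counts(config: SimConfig, n_genes: int | None = None) -> CountSim:
    """Two-condition negative-binomial count matrix with known DE truth.

    Exactly ``round(de_fraction · n)`` genes differ between groups by
    ``lfc_magnitude`` log2 units (random sign, BF relative to LD); counts
    are gamma-Poisson with the configured per-gene overdispersion, and each
    sample carries a depth multiplier drawn from ``depth_range``.
    Unpacks as ``counts, lengths, groups, truth = sim_counts(...)``.
    """
    if config.n_samples_per_group < 2:
        raise ConfigurationError("n_samples_per_group must be >= 2")
    rng = config.rng(4)
    n = n_genes if n_genes is not None else config.n_genes
    genes = [f"simG{i + 1:04d}" for i in range(n)]
    base = rng.lognormal(mean=math.log(100.0), sigma=1.2, size=n)
    n_de = round(config.de_fraction * n)
    de_idx = rng.permutation(n)[:n_de]
    lfc = np.zeros(n)
    lfc[de_idx] = config.lfc_magnitude * rng.choice([-1.0, 1.0], size=n_de)

    nspg = config.n_samples_per_group
    samples = [f"LD_{j + 1}" for j in range(nspg)] + [f"BF_{j + 1}" for j in range(nspg)]
    groups = pd.Series(["LD"] * nspg + ["BF"] * nspg, index=samples, name="group")
    depth = rng.uniform(config.depth_range[0], config.depth_range[1], size=2 * nspg)

    mat = np.empty((n, 2 * nspg), dtype=np.int64)
    for j, sample in enumerate(samples):
        mu = base * np.where(groups[sample] == "BF", 2.0 ** lfc, 1.0) * depth[j]
        if config.nb_dispersion > 0:
            lam = rng.gamma(shape=1.0 / config.nb_dispersion,
                            scale=mu * config.nb_dispersion)
            mat[:, j] = rng.poisson(lam)
        else:
            mat[:, j] = rng.poisson(mu)
    counts = pd.DataFrame(mat, index=pd.Index(genes, name="gene_id"), columns=samples)
    lengths = pd.Series(rng.integers(400, 4000, size=n), index=counts.index,
                        name="length")
    de_truth = pd.DataFrame({"gene_id": genes, "is_de": lfc != 0.0,
                             "true_log2fc": lfc}).set_index("gene_id")
    return CountSim(counts, lengths, groups, de_truth,
                    pd.Series(depth, index=samples, name="depth"))


# ----------------------------------------------------------------- pipeline

def simulate(config: SimConfig, outdir: str | Path) -> TruthSet:
    """Run the full generator and write every artifact as plain text."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genome = gen_genome(config)
    transcripts, truth = gen_annotation(genome, config)
    reads, aln_rows, labels = sim_flnc_reads(genome, transcripts, truth, config)
    counts, lengths, groups, de_truth = sim_counts(config)
    truth.de = de_truth

    cio.write_fasta(genome, outdir / "genome.fa")
    cio.write_gtf(transcripts, outdir / "annotation.gtf")
    cio.write_fasta(reads, outdir / "reads.fa")
    cio.write_bed12(aln_rows, outdir / "true_alignments.bed")
    cio.write_tsv(labels, outdir / "read_truth.tsv")
    cio.write_tsv(counts.join(lengths).reset_index(), outdir / "counts.tsv")
    cio.write_tsv(groups.rename_axis("sample").reset_index(), outdir / "samples.tsv")
    cio.write_tsv(de_truth.reset_index(), outdir / "de_truth.tsv")
    return truth
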