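# Methods

## What the pipeline models

The package treats a hybrid transcriptome experiment as a chain of
well-defined decision rules over three kinds of objects: reads (CCS
sequences with primer/polyA annotations), transcript models (stranded
exon chains on a chromosome), and count matrices (features × samples).
Each stage is a pure function of its inputs, so every rule can be
validated on synthetic data with known truth.

Coordinates are 0-based half-open internally; GTF is written 1-based
inclusive and BED12 0-based half-open, following the formats'
definitions.

## Read classification

A read is **full-length** iff the 5' primer matches in the leading
window (2× primer length), the reverse-complemented 3' primer matches in
the trailing window, and a polyA tail is present; **FLNC** additionally
requires zero primer matches outside both terminal windows (internal
copies are concatemer evidence).  Reads shorter than 50 nt or longer
than 15,000 nt are filtered out before the full-length test.  The three
categories filtered-short / non-full-length / full-length partition any
input, and FLNC ⊆ full-length — the arithmetic the study's library
tables obey.

Primer matching is a Hamming-distance scan (default ≤ 2 mismatches);
the detector therefore misses primers hit by indels, which is visible as
a small FLNC undercount at nonzero error rates and disappears at error
rate 0.  The polyA rule requires at least `polya_min_length` (default
20) A bases inside a window whose A-fraction is at least
`polya_min_purity` (default 0.9), ending within 50 nt of the 3' primer.
Requiring the A *count* rather than only the window fraction makes the
length bar exact: 19 A's can never satisfy a 20-base minimum regardless
of purity.  Both defaults are package choices; the source protocol
names no matcher or polyA thresholds.

Short-read QC discards a read on any of: adaptor substring hit, unknown
bases over 10%, bases under Phred 20 over 50%.  Both fraction tests are
strict inequalities, so exactly 10% N is kept.

## Alignment quality

Local PID = 100·matches/aligned-columns; global PID =
100·matches/read-length (global ≤ local always).  Categories: no
placement → unmapped; ≥ 2 placements with scores (matches − mismatches −
gaps) within 1% of the best → multiple-best; unique best under the local
PID threshold (default 90, flag-exposed) → low PID; else high quality.
The threshold and the 1% tie band are package choices — the study names
the four categories but not its cutoffs — and the filter is applied to
the local PID while both PIDs are reported.  Merging two rounds keeps,
per read, the better category (high quality > low PID > multiple-best >
unmapped; ties broken by local PID), so merging can never decrease the
high-quality count.

## Cataloguing

Two transcripts are directly linked when they share chromosome and
strand, their spans overlap at least 20% — of the *shorter* span by
default; `denominator={shorter,longer,union}` is exposed because the
source rule's denominator is ambiguous — and at least one exon pair
overlaps strictly more than 20% of the shorter exon.  Loci are connected
components of this relation, implemented as union-find over per-strand
sweeps and verified against an all-pairs transitive-closure oracle.

Collapse groups multi-exon transcripts by identical intron chains and
keeps the longest spliced representative (ties by id for determinism);
support is conserved.  Mono-exon transcripts merge by containment — an
extension, since the identical-splice-site rule is silent about them.
An isoform is full-length when its intron chain contains the first
splice donor (strand-aware: the donor nearest the transcript 5' end) of
any overlapping same-strand reference isoform.

Gene novelty uses the locus span as denominator: novel iff no reference
overlap, best same-strand overlap < 20%, or ≥ 20% overlap only
antisense.  Isoform novelty matches splice sites exactly
(a ±N fuzz window exists, default 0); candidate-novel isoforms need ≥ 2
supporting FLNCs or one with local PID > 99, and failures are discarded
*before* any summary.  Locus length for the length-bin table is the
spliced length of the longest member isoform (genomic span available by
flag); the source table does not state its statistic.

## Splicing events, APA, fusions

Events are pairwise between isoforms of one locus, deduplicated by
(type, coordinates): ES when one intron of a chain runs
donor-to-acceptor across one or more consecutive exons of the other (one
event per skipped exon); AA/AD when two introns share a donor (acceptor)
but not the acceptor (donor), strand-aware, excluding intron pairs
already explained by an ES skip so a cassette exon is not double-counted
as donor+acceptor shifts; IR when an intron of one chain lies inside an
exon of the other.  The enumeration is validated against an independent
exhaustive oracle on random loci of up to 4 isoforms.

APA clusters FLNC 3'-end positions with single-linkage at a 20-nt
window (package default), takes the support-weighted mode (smallest on
ties) as the site, drops sites with < 2 reads, and flags a locus APA at
≥ 2 surviving sites.  Fusion candidates need two read fragments on
distinct loci, each ≥ 10% of the read, jointly ≥ 90%; the thresholds are
package defaults (the study used proprietary software) and are exposed
as parameters.

## Coding potential and lncRNA

ORFs are scanned in the three forward frames only — FLNC orientation is
fixed by the primers — reporting every ATG-initiated ORF (complete or
3'-partial) plus each frame's leading open stretch (5'-partial), filtered
at ≥ 100 aa.  The Fickett TESTCODE statistic uses the published
position-asymmetry and composition lookup tables; its attainable range
with those tables is [0.426, 1.024].  Coding probability is a logistic
combination of ORF coverage, log10 ORF length and Fickett score; the
weights were fit once on a synthetic set (long-ORF transcripts vs their
base-shuffled versions, seed 2024) and ship as package data so the
probability is deterministic.  Hexamer-usage features are deliberately
omitted.  The lncRNA filter is conjunctive — length ≥ 200 nt AND
probability ≤ 0.5 AND no protein-database hit — because the disjunctive
reading of the source criterion ("≥200 nt *or* probability ≤0.5") would
label nearly every transcript non-coding.  Protein-database hits are an
input column; homology search itself is out of scope.

## Quantification and differential expression

FPKM = count/(length/10³)/(library/10⁶).  Size factors are
median-of-ratios over features nonzero in all samples, falling back with
a warning to library-size ratios.  The DE engine is a documented NB Wald
test, not a DESeq2 re-implementation: per feature, group means of
normalized counts, a pooled within-group moment estimate of the NB
dispersion floored at 10⁻⁸, log2FC = log2((μ_BF+ε)/(μ_LD+ε)) with
ε = 0.5 (configurable), a delta-method standard error from
Var(mean) = (μ + αμ²)/n, and a two-sided p from a t reference with
n₁+n₂−2 degrees of freedom — the small-sample reference that keeps the
type-I error at the nominal level with four replicates per group, where
a normal reference is too liberal.  Features with an
all-zero group are skipped and recorded.  BH adjustment is an in-house
step-up checked against the statsmodels reference.  DE requires
padj < 0.05, |log2FC| > 1 and FPKM > 0 in at least one sample (an
all-sample switch exists; the FPKM ≥ 1-in-all-samples subset is the
enrichment background).  Fold changes are emitted BF/LD with a
`flip_orientation` switch, since published per-gene tables appear to
print the opposite orientation.

## Summary statistics

The trait comparisons are rebuilt from printed mean ± SEM (n = 4):
t = (m₁−m₂)/√(SEM₁²+SEM₂²), df = 6, two-sided p (Welch available by
flag).  This reproduces seven of the nine printed p-values exactly at
two decimals; pH 24 h computes to 0.31 (printed 0.28) and water-holding
to 0.36 (printed 0.32).  No test computable from unpaired summaries
reproduces those two — the muscles come from the same four animals, so
the original analysis was plausibly paired, which mean ± SEM summaries
cannot reconstruct.  The acceptance suite keeps the strict all-nine
check and it fails by design; the unit suite asserts the seven exact
matches and a 0.04 bound on the rest.

Enrichment is the hypergeometric upper tail per term with BH FDR and a
0.05 significance bar, validated against exhaustive enumeration for
N ≤ 30.

## The synthetic generator

`SimConfig` defaults describe the study conditions this artifact is
tested under: multi-exon genes (3–8 exons of 80–300 nt, introns
60–400 nt) with 2–4 isoforms derived by cassette-exon skips, ±6–30 nt
donor/acceptor shifts, intron retentions and 100–300 nt alternative 3'
ends; canonical GT/AG boundaries written into the genome; reads at 1%
error (substitutions 80%, indels 20%), 15%/10% 5'/3' truncation, 2%
chimeras, 5% short fragments, a 30-nt polyA and the SMARTer-style
primer pair; counts with 4 samples per group, 10% true DE at |log2FC| =
2, NB dispersion 0.05 and 0.7–1.4× depth multipliers.  Chimeras are
two-fragment by design, with partners sampled so each fragment is
≥ 10% of the read and both jointly ≥ 90% — the geometry of a
two-template concatemer artifact and the regime in which split-read
detection is well defined.  Truncation rates are arbitrary (the source
protocol reports none) and config-exposed.

What the generator does not emulate: realistic long-read error profiles
(errors are i.i.d. per base), quality values, reverse-transcription
template switching, expression-weighted read sampling, genome repeats or
paralogy (uniform random sequence), and biological codon usage.  Tests
passing on this data therefore demonstrate that the *rules* are
implemented correctly and are internally consistent — not that the
pipeline is robust to every artifact of real PacBio data.

## Problem sizes

The default analyses run 20–30 genes, ~50–85 isoforms and 300–1,500
reads for structural stages, and 2,000–5,000 genes × 8 samples for the
count-based stages; these sizes give every statistic a comfortable
sample (e.g. 5,000 null genes for the type-I estimate) while the whole
suite and the acceptance script each finish in well under a minute.

## Known limitations

- Primer detection is substitution-only (Hamming); indel-hit primers are
  missed, slightly deflating FLNC counts at nonzero error rates.
- The NB Wald test uses moment dispersion per gene with no shrinkage;
  it is calibrated at the simulated conditions but less efficient than
  shrinkage estimators on real data.
- The coding model is trained on synthetic composition signal only and
  should not be read as a CPAT replacement for real transcriptomes.
- AS events are enumerated pairwise and deduplicated by coordinates;
  complex nestings (mutually exclusive exons, alternative first/last
  exons) are not separate types, matching the four-type report the
  pipeline targets.
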