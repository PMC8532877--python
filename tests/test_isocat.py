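"""Loci clustering, isoform collapse, novelty rules, length summaries."""

import numpy as np
import pytest

from capriseq.isocat import (Catalogue, build_catalogue, classify_gene_novelty,
                             classify_isoform_novelty, cluster_loci,
                             collapse_isoforms, flag_full_length, locus_length,
                             locus_length_summary, transcripts_linked)
from capriseq.models import IsoformRecord, Locus, TranscriptModel
from capriseq.workflow import (flnc_transcript_models, recovered_chain_sets,
                               simulated_chain_sets)


def _tx(tid, exons, strand="+", chrom="chr1", gene=None, support=None):
    return TranscriptModel(tid, chrom, strand, exons, gene_id=gene,
                           support=support or [])


# ------------------------------------------------------------- clustering

def test_same_strand_overlap_links_one_locus():
    a = _tx("a", [(0, 500), (800, 1000)])
    b = _tx("b", [(400, 600), (800, 1000)])  # 60% span overlap, shared exon
    loci = cluster_loci([a, b])
    assert len(loci) == 1 and len(loci[0].transcripts) == 2


def test_opposite_strands_never_cluster():
    a = _tx("a", [(0, 500), (800, 1000)], strand="+")
    b = _tx("b", [(0, 500), (800, 1000)], strand="-")
    assert len(cluster_loci([a, b])) == 2


def test_weak_span_overlap_splits_loci():
    # 10% of the shorter span: below the 20% bar
    a = _tx("a", [(0, 1000)])
    b = _tx("b", [(900, 1900)])
    assert len(cluster_loci([a, b])) == 2


def test_span_overlap_boundary_is_inclusive():
    # exactly 20% of the shorter span qualifies ("reached 20%")
    a = _tx("a", [(0, 100), (800, 1000)])
    b = _tx("b", [(800, 900), (1700, 1800)])
    assert transcripts_linked(a, b)
    assert len(cluster_loci([a, b])) == 1


def test_exon_overlap_must_exceed_20_percent():
    # spans overlap but the only exon pair overlaps exactly 20% of the
    # shorter exon: the strict "more than 20%" test fails
    a = _tx("a", [(0, 100), (900, 1000)])
    b = _tx("b", [(80, 180)])
    assert not transcripts_linked(a, b)


def test_clustering_is_transitive_through_a_bridge():
    a = _tx("a", [(0, 400)])
    bridge = _tx("b", [(300, 700)])
    c = _tx("c", [(600, 1000)])
    loci = cluster_loci([a, bridge, c])
    assert len(loci) == 1


def test_cluster_matches_brute_force_transitive_closure():
    """Production sweep equals an all-pairs connected-components oracle."""
    from oracles import brute_force_loci, random_transcripts
    rng = np.random.default_rng(42)
    for _ in range(30):
        tx = random_transcripts(rng, int(rng.integers(5, 100)))
        oracle = brute_force_loci(tx, transcripts_linked)
        ours = {frozenset(t.transcript_id for t in locus.transcripts)
                for locus in cluster_loci(tx)}
        assert ours == oracle


# --------------------------------------------------------------- collapse

def test_identical_chains_keep_longest_representative():
    a = _tx("a", [(0, 100), (200, 300)], support=[("r1", 95.0)])
    b = _tx("b", [(0, 150), (200, 300)], support=[("r2", 99.5)])  # same chain? no
    # same intron chain requires identical intron coordinates:
    b = _tx("b", [(0, 100), (200, 400)], support=[("r2", 99.5)])
    locus = Locus("L", "chr1", "+", [a, b])
    records = collapse_isoforms(locus)
    assert len(records) == 1
    assert records[0].representative.spliced_length == 300  # the longer one
    assert records[0].support_count == 2
    assert records[0].max_support_pid == 99.5


def test_distinct_chains_stay_separate():
    a = _tx("a", [(0, 100), (200, 300)])
    b = _tx("b", [(0, 100), (250, 300)])
    records = collapse_isoforms(Locus("L", "chr1", "+", [a, b]))
    assert len(records) == 2


def test_collapse_idempotent_and_support_conserving():
    rng = np.random.default_rng(3)
    tx = []
    for i in range(30):
        s = int(rng.integers(0, 3))
        chain = [[(0, 100), (200, 300)], [(0, 100), (250, 300)],
                 [(10, 90), (200, 300 + 10 * i % 40)]][s]
        tx.append(_tx(f"t{i}", chain))
    locus = Locus("L", "chr1", "+", tx)
    once = collapse_isoforms(locus)
    assert sum(r.support_count for r in once) == len(tx)
    again = collapse_isoforms(
        Locus("L", "chr1", "+", [r.representative for r in once]))
    assert {r.intron_chain for r in again} == {r.intron_chain for r in once}
    chains = [r.intron_chain for r in once if r.is_multi_exon]
    assert len(chains) == len(set(chains))


def test_mono_exon_containment_merge():
    big = _tx("big", [(0, 1000)])
    small = _tx("small", [(100, 500)])
    apart = _tx("apart", [(500, 1600)])  # overlaps but not contained
    records = collapse_isoforms(Locus("L", "chr1", "+", [big, small, apart]))
    assert len(records) == 2
    rec_big = next(r for r in records if r.representative.spliced_length == 1000)
    assert rec_big.support_count == 2


# ------------------------------------------------------------ full length

def _iso(tid, exons, strand="+", support_count=1, pid=100.0):
    rep = _tx(tid, exons, strand=strand)
    return IsoformRecord(tid, rep, support_count, pid)


def test_full_length_requires_reference_first_donor():
    ref = [_tx("ref", [(0, 100), (200, 300), (400, 500)], gene="G")]
    shares_first = _iso("q1", [(50, 100), (200, 300), (400, 520)])
    assert flag_full_length(shares_first, ref) is True
    starts_downstream = _iso("q2", [(250, 300), (400, 520)])
    assert flag_full_length(starts_downstream, ref) is False


def test_full_length_minus_strand_uses_highest_donor():
    # minus strand: transcript 5' end is the highest coordinate, so the
    # first donor is the genomic END of the last intron (400 here)
    ref = [_tx("ref", [(0, 100), (200, 300), (400, 500)], strand="-", gene="G")]
    q_with_last_intron = _iso("q1", [(250, 300), (400, 500)], strand="-")
    assert flag_full_length(q_with_last_intron, ref) is True
    q_missing_it = _iso("q2", [(0, 100), (200, 320)], strand="-")
    assert flag_full_length(q_missing_it, ref) is False


def test_full_length_undefined_for_mono_exon():
    with pytest.raises(ValueError):
        flag_full_length(_iso("q", [(0, 500)]), [])


# ---------------------------------------------------------------- novelty

REF = [_tx("refA.1", [(0, 300), (500, 800)], gene="refA"),
       _tx("refB.1", [(5000, 5400)], gene="refB")]


def test_gene_novelty_rules():
    no_overlap = Locus("L1", "chr1", "+", [_tx("x", [(2000, 2500)])])
    assert classify_gene_novelty(no_overlap, REF)[0] == "novel"

    weak = Locus("L2", "chr1", "+", [_tx("x", [(700, 3000)])])  # 100/2300 ~ 4%
    assert classify_gene_novelty(weak, REF)[0] == "novel"

    antisense = Locus("L3", "chr1", "-", [_tx("x", [(0, 800)], strand="-")])
    assert classify_gene_novelty(antisense, REF)[0] == "novel"

    known = Locus("L4", "chr1", "+", [_tx("x", [(100, 700)])])
    novelty, matched = classify_gene_novelty(known, REF)
    assert novelty == "known" and matched == ("refA",)


def test_isoform_novelty_known_when_all_sites_annotated():
    iso = _iso("q", [(0, 300), (500, 800)])
    assert classify_isoform_novelty(iso, REF) == "known"


def test_isoform_novelty_support_rule():
    novel_site = [(0, 300), (520, 800)]  # shifted acceptor
    assert classify_isoform_novelty(
        _iso("q1", novel_site, support_count=2, pid=95.0), REF) == "novel"
    assert classify_isoform_novelty(
        _iso("q2", novel_site, support_count=1, pid=99.5), REF) == "novel"
    assert classify_isoform_novelty(
        _iso("q3", novel_site, support_count=1, pid=98.5), REF) == "discarded"


def test_mono_exon_novelty_requires_identical_reference_exon():
    assert classify_isoform_novelty(_iso("q", [(5000, 5400)]), REF) == "known"
    assert classify_isoform_novelty(
        _iso("q", [(5000, 5500)], support_count=3), REF) == "novel"


def test_reference_only_catalogue_is_entirely_known(clean_run):
    reference = clean_run.transcripts
    cat = build_catalogue(reference, reference=reference)
    assert all(locus.novelty == "known" for locus in cat.loci)
    assert all(r.novelty == "known" for r in cat.all_isoforms())
    assert cat.discarded == 0


# --------------------------------------------------------------- summary

def test_length_binning_counts():
    df = locus_length_summary([500, 1500, 2500, 3500])
    assert df["count"].tolist() == [1, 1, 1, 1]
    assert df["pct"].tolist() == [25.0, 25.0, 25.0, 25.0]


def test_length_bin_boundaries():
    df = locus_length_summary([999, 1000, 2000, 3000])
    assert df["count"].tolist() == [1, 1, 1, 1]


def test_locus_length_statistics():
    locus = Locus("L", "chr1", "+", [
        _tx("a", [(0, 400), (900, 1000)]), _tx("b", [(0, 1000)])])
    assert locus_length(locus, statistic="spliced_longest") == 1000
    assert locus_length(locus, statistic="span") == 1000


# ------------------------------------------------------------ closed loop

def test_exact_recovery_of_simulated_loci_and_chains(clean_run, clean_catalogue):
    assert len(clean_catalogue.loci) == len(clean_run.truth.genes)
    assert recovered_chain_sets(clean_catalogue) == \
        simulated_chain_sets(clean_run.truth)


def test_recovered_loci_match_simulated_gene_membership(clean_run, clean_catalogue):
    for locus in clean_catalogue.loci:
        genes = {t.gene_id for t in locus.transcripts}
        assert len(genes) == 1
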