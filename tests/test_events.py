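"""AS event enumeration, APA clustering, fusion calling."""

import itertools

import numpy as np
import pytest

from capriseq.events import (APASite, SplitSegment, as_summary, detect_apa,
                             detect_fusion, detect_fusions,
                             enumerate_as_events)
from capriseq.models import TranscriptModel


def _tx(tid, exons, strand="+"):
    return TranscriptModel(tid, "chr1", strand, exons)


# ------------------------------------------------------- pairwise events

def test_cassette_exon_gives_exactly_one_es_event():
    full = _tx("a", [(0, 100), (200, 300), (400, 500)])
    skipped = _tx("b", [(0, 100), (400, 500)])
    events = enumerate_as_events([full, skipped])
    assert len(events) == 1
    e = events[0]
    assert e.type == "ES" and tuple(e.coordinates) == (200, 300)


def test_double_skip_yields_two_es_events():
    full = _tx("a", [(0, 100), (200, 300), (400, 500), (600, 700)])
    skipped = _tx("b", [(0, 100), (600, 700)])
    events = enumerate_as_events([full, skipped])
    assert sorted((e.type, tuple(e.coordinates)) for e in events) == [
        ("ES", (200, 300)), ("ES", (400, 500))]


def test_acceptor_shift_is_aa_not_ad():
    a = _tx("a", [(0, 100), (200, 300)])
    b = _tx("b", [(0, 100), (220, 300)])
    events = enumerate_as_events([a, b])
    assert [e.type for e in events] == ["AA"]


def test_donor_shift_is_ad_on_plus_and_aa_on_minus():
    a_plus = _tx("a", [(0, 100), (200, 300)])
    b_plus = _tx("b", [(0, 80), (200, 300)])
    assert [e.type for e in enumerate_as_events([a_plus, b_plus])] == ["AD"]
    # the same genomic change on the minus strand shifts the ACCEPTOR
    a_minus = _tx("a", [(0, 100), (200, 300)], strand="-")
    b_minus = _tx("b", [(0, 80), (200, 300)], strand="-")
    assert [e.type for e in enumerate_as_events([a_minus, b_minus])] == ["AA"]


def test_intron_retention_detected_both_directions():
    spliced = _tx("a", [(0, 100), (200, 300)])
    retained = _tx("b", [(0, 300)])
    events = enumerate_as_events([spliced, retained])
    assert [(e.type, tuple(e.coordinates)) for e in events] == [("IR", (100, 200))]
    assert [e.type for e in enumerate_as_events([retained, spliced])] == ["IR"]


def test_single_isoform_locus_has_no_events():
    assert enumerate_as_events([_tx("a", [(0, 100), (200, 300)])]) == []


def test_enumeration_symmetric_and_translation_invariant():
    a = _tx("a", [(0, 100), (200, 300), (400, 500)])
    b = _tx("b", [(0, 100), (400, 500)])
    c = _tx("c", [(0, 100), (220, 300), (400, 500)])
    fwd = {(e.type, tuple(e.coordinates)) for e in enumerate_as_events([a, b, c])}
    rev = {(e.type, tuple(e.coordinates)) for e in enumerate_as_events([c, b, a])}
    assert fwd == rev
    shift = 10_000
    moved = [_tx(t.transcript_id, [(s + shift, e + shift) for s, e in t.exons])
             for t in (a, b, c)]
    shifted = {(e.type, tuple(np.array(e.coordinates) - shift))
               for e in enumerate_as_events(moved)}
    assert {(t, tuple(map(int, c))) for t, c in shifted} == fwd


# ----------------------------------------------------- brute-force oracle

def test_enumeration_equals_exhaustive_pairwise_oracle():
    from oracles import oracle_pair_events, random_locus
    rng = np.random.default_rng(11)
    for _ in range(60):
        isoforms = random_locus(rng)
        expected = set()
        for x, y in itertools.combinations(isoforms, 2):
            expected |= oracle_pair_events(x, y)
        got = {(e.type, tuple(e.coordinates))
               for e in enumerate_as_events(isoforms)}
        assert got == {(t, tuple(c)) for t, c in expected}


# ---------------------------------------------------------------- summary

def test_as_summary_ir_fraction():
    ev = enumerate_as_events([
        _tx("a", [(0, 100), (200, 300), (400, 500)]),
        _tx("b", [(0, 100), (400, 500)]),
        _tx("c", [(0, 300), (400, 500)]),
    ])
    counts, ir = as_summary(ev)
    assert counts["ES"] >= 1 and counts["IR"] >= 1
    assert ir == counts["IR"] / sum(counts.values())


def test_as_summary_empty_is_flagged():
    counts, ir = as_summary([])
    assert sum(counts.values()) == 0 and ir is None


def test_simulated_ir_share_matches_configured_rates():
    # with all four splice event classes at the same rate the IR share of
    # the generated event mix should sit at 1/4 (binomial tolerance)
    from capriseq.simdata import SimConfig, gen_annotation, gen_genome
    rates = {"ES": 0.3, "AA": 0.3, "AD": 0.3, "IR": 0.3, "APA": 0.0}
    cfg = SimConfig(seed=31, n_genes=120, n_chromosomes=8,
                    chromosome_length=200_000, as_event_rates=rates,
                    isoforms_per_gene=(2, 2))
    _, truth = gen_annotation(gen_genome(cfg), cfg)
    labels = [e for g in truth.genes.values() for e in g.as_events]
    share = labels.count("IR") / len(labels)
    se = np.sqrt(0.25 * 0.75 / len(labels))
    assert abs(share - 0.25) < 3 * se + 0.02


# -------------------------------------------------------------------- APA

def test_apa_support_rule():
    sites, is_apa = detect_apa([1000, 1000, 1000, 1500, 1500], window=20)
    assert [(s.position, s.support) for s in sites] == [(1000, 3), (1500, 2)]
    assert is_apa

    sites, is_apa = detect_apa([1000, 1000, 1000, 1500], window=20)
    assert [(s.position, s.support) for s in sites] == [(1000, 3)]
    assert not is_apa


def test_apa_window_merges_nearby_ends():
    sites, _ = detect_apa([1000, 1010], window=20)
    assert len(sites) == 1 and sites[0].support == 2
    assert sites[0].position == 1000  # tie on counts -> smallest position


def test_apa_invariant_to_input_order():
    ends = [1500, 1000, 1010, 1502, 990]
    a, _ = detect_apa(ends, window=20)
    b, _ = detect_apa(ends[::-1], window=20)
    assert [(s.position, s.support) for s in a] == \
        [(s.position, s.support) for s in b]


# ----------------------------------------------------------------- fusion

def test_split_read_across_two_loci_is_a_candidate():
    segs = [SplitSegment(0, 500, "locusA"), SplitSegment(510, 1000, "locusB")]
    cand = detect_fusion("r", segs, 1000)
    assert cand is not None
    assert (cand.partner_5prime, cand.partner_3prime) == ("locusA", "locusB")
    assert cand.breakpoints == (500, 510)


def test_read_within_one_locus_is_not_a_candidate():
    segs = [SplitSegment(0, 500, "locusA"), SplitSegment(510, 1000, "locusA")]
    assert detect_fusion("r", segs, 1000) is None


def test_tiny_or_uncovering_segments_rejected():
    segs = [SplitSegment(0, 50, "locusA"), SplitSegment(60, 1000, "locusB")]
    assert detect_fusion("r", segs, 1000) is None  # 5% segment
    segs = [SplitSegment(0, 400, "locusA"), SplitSegment(420, 800, "locusB")]
    assert detect_fusion("r", segs, 1000) is None  # 80% combined


def test_closed_loop_fusion_recall_is_perfect():
    from capriseq.simdata import SimConfig
    from capriseq.workflow import fusion_candidates_from_truth, run_simulation
    cfg = SimConfig(seed=6, read_error_rate=0.0, chimera_rate=0.15,
                    trunc5_rate=0.0, trunc3_rate=0.0, short_read_rate=0.0,
                    n_reads=300)
    run = run_simulation(cfg)
    true_chimeras = {rid for rid, rt in run.truth.reads.items()
                     if rt.category == "chimeric"
                     and rt.segments[0].gene_id != rt.segments[1].gene_id}
    called = {c.read_id for c in fusion_candidates_from_truth(run)}
    assert true_chimeras and called >= true_chimeras
    assert called == true_chimeras  # and no false positives
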