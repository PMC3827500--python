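"""Splice-graph bubbles, event classification, junction paths, and PSI."""

import random

import numpy as np
import pytest

import spliceward as sw
from spliceward.events import SRC, SNK, build_splice_graph


def _tx(gene, tid, strand, exons, chrom="c"):
    return sw.TranscriptModel(gene, tid, chrom, strand, exons)


# ---------------------------------------------------------------------------
# Graph construction
# ---------------------------------------------------------------------------


def test_graph_single_transcript_linear_path():
    sg = build_splice_graph([_tx("g", "t", "+", [(0, 10), (60, 80), (130, 150)])])
    path = sg.paths["t"]
    assert path[0] == SRC and path[-1] == SNK
    assert len(path) == 8  # six boundary nodes + terminals


def test_graph_duplicate_transcripts_idempotent():
    a = _tx("g", "t1", "+", [(0, 10), (60, 80)])
    b = _tx("g", "t2", "+", [(0, 10), (60, 80)])
    sg1 = build_splice_graph([a])
    sg2 = build_splice_graph([a, b])
    assert set(sg1.graph.edges) == set(sg2.graph.edges)


def test_graph_mixed_strands_rejected():
    with pytest.raises(sw.FormatError):
        build_splice_graph(
            [_tx("g", "t1", "+", [(0, 10)]), _tx("g", "t2", "-", [(0, 10)])]
        )


# ---------------------------------------------------------------------------
# Enumeration and classification
# ---------------------------------------------------------------------------


def _cassette_annotation():
    inc = _tx("g", "tI", "+", [(0, 100), (200, 300), (400, 500)])
    exc = _tx("g", "tE", "+", [(0, 100), (400, 500)])
    return sw.Annotation([inc, exc])


def test_cassette_exon_event():
    (ev,) = sw.enumerate_events(_cassette_annotation())
    assert ev.event_type == "exonskip"
    assert ev.structure_code == "0,1-2^"
    assert ev.junctions_inclusion == {("c", 100, 200), ("c", 300, 400)}
    assert ev.junctions_exclusion == {("c", 100, 400)}
    assert ev.is_internal


def test_five_prime_trim_excluded():
    # two transcripts identical except the start of the same first exon
    a = _tx("g", "t1", "+", [(0, 100), (200, 300)])
    b = _tx("g", "t2", "+", [(30, 100), (200, 300)])
    assert sw.enumerate_events(sw.Annotation([a, b])) == []
    # minus strand: the five-prime end is the right edge of the last exon
    c = _tx("g", "t1", "-", [(0, 100), (200, 300)])
    d = _tx("g", "t2", "-", [(0, 100), (200, 270)])
    assert sw.enumerate_events(sw.Annotation([c, d])) == []


def test_enumeration_invariant_to_transcript_order():
    ann = _cassette_annotation()
    ids_fwd = [e.event_id for e in sw.enumerate_events(ann)]
    ann_rev = sw.Annotation(list(reversed(ann.transcripts)))
    assert [e.event_id for e in sw.enumerate_events(ann_rev)] == ids_fwd


@pytest.mark.parametrize("etype", list(sw.FixtureConfig().event_fractions))
@pytest.mark.parametrize("minus", [0.0, 1.0])
def test_fixture_events_recovered_by_enumeration(etype, minus):
    """Native enumeration recovers every planted event: type, junction
    sets, and inclusion orientation."""
    cfg = sw.FixtureConfig(
        n_genes=5, event_fractions={etype: 1.0}, minus_fraction=minus
    )
    fx = sw.make_toy_fixture(cfg, seed=11)
    events = sw.enumerate_events(fx.annotation)
    by_gene = {e.gene_id: e for e in events}
    assert len(events) == len(fx.manifest["events"]) == 5
    for planted in fx.manifest["events"]:
        ev = by_gene[planted["gene_id"]]
        assert ev.event_type == planted["event_type"]
        assert ev.junctions_inclusion == {
            tuple(j) for j in planted["inclusion_junctions"]
        }
        assert ev.junctions_exclusion == {
            tuple(j) for j in planted["exclusion_junctions"]
        }


def test_event_junction_sets_disjoint_and_within_flanks(toy):
    for ev in sw.enumerate_events(toy.annotation):
        assert not (ev.junctions_inclusion & ev.junctions_exclusion)
        if ev.is_internal:
            for _, s, e in ev.junctions_inclusion | ev.junctions_exclusion:
                assert ev.flank_left <= s and e <= ev.flank_right


# ---------------------------------------------------------------------------
# PSI quantification
# ---------------------------------------------------------------------------


def test_psi_per_junction_normalization():
    (ev,) = sw.enumerate_events(_cassette_annotation())
    cov = {("c", 100, 200): 15, ("c", 300, 400): 15, ("c", 100, 400): 5}
    q = sw.quantify_event(ev, cov)
    assert q.psi == pytest.approx(15 / (15 + 5))  # 30 reads over 2 junctions vs 5
    sym = {("c", 100, 200): 10, ("c", 300, 400): 10, ("c", 100, 400): 10}
    assert sw.quantify_event(ev, sym).psi == pytest.approx(0.5)


def test_psi_degenerate_cases():
    (ev,) = sw.enumerate_events(_cassette_annotation())
    only_inc = {("c", 100, 200): 10, ("c", 300, 400): 10}
    assert sw.quantify_event(ev, only_inc).psi == pytest.approx(1.0)
    assert np.isnan(sw.quantify_event(ev, {}).psi)


def test_psi_swap_symmetry():
    (ev,) = sw.enumerate_events(_cassette_annotation())
    cov = {("c", 100, 200): 24, ("c", 300, 400): 18, ("c", 100, 400): 7}
    psi = sw.quantify_event(ev, cov).psi
    assert sw.quantify_event(ev.swapped(), cov).psi == pytest.approx(1 - psi)


def test_retintron_psi_uses_readthrough():
    a = _tx("g", "tS", "+", [(0, 100), (200, 300)])
    b = _tx("g", "tR", "+", [(0, 300)])
    (ev,) = sw.enumerate_events(sw.Annotation([a, b]))
    assert ev.event_type == "retintron"
    assert ev.junctions_inclusion == {("c", 100, 200)}
    assert ev.junctions_exclusion == set()
    cov = {("c", 100, 200): 30}
    rt = {("c", 100, 200): (12, 18)}  # mean 15 read-through
    q = sw.quantify_event(ev, cov, rt)
    assert q.psi == pytest.approx(30 / (30 + 15))
    assert not sw.quantify_event(ev, cov, None).quantifiable


def test_neighbor_confounding_counts_external_joins():
    # cassette plus an isoform splicing from the cassette exon to a distal exon
    ann = sw.Annotation(
        [
            _tx("g", "tI", "+", [(0, 100), (200, 300), (400, 500)]),
            _tx("g", "tE", "+", [(0, 100), (400, 500)]),
            _tx("g", "tX", "+", [(0, 100), (200, 300), (600, 700)]),
        ]
    )
    events = {e.event_type: e for e in sw.enumerate_events(ann)}
    ev = next(e for e in events.values() if e.structure_code == "0,1-2^")
    cov = {
        ("c", 100, 200): 10,
        ("c", 300, 400): 10,
        ("c", 100, 400): 10,
        ("c", 300, 600): 9,  # join leaving the event through the cassette exon
    }
    assert sw.neighbor_confounding(ev, cov) == 9
    isolated = {k: v for k, v in cov.items() if k != ("c", 300, 600)}
    assert sw.neighbor_confounding(ev, isolated) == 0
    assert sw.neighbor_confounding(ev, {}) == 0


# ---------------------------------------------------------------------------
# External event definitions
# ---------------------------------------------------------------------------


def _asta_line(chrom, strand, gene, flanks, structure, chains, txs):
    attrs = (
        f'transcript_id "{txs}"; gene_id "{gene}"; flanks "{flanks}"; '
        f'structure "{structure}"; splice_chain "{chains}";'
    )
    return f"{chrom}\tasta\tas_event\t1\t500\t.\t{strand}\t.\t{attrs}\n"


def test_parse_astalavista_matches_native_enumeration(tmp_path):
    ann = _cassette_annotation()
    (native,) = sw.enumerate_events(ann)
    # cassette: flanks are the donor at 100 and the acceptor at 401 (1-based)
    line = _asta_line(
        "c", "+", "g", "100^,401-", "0,1-2^", ",201-300^", "tE,tI"
    )
    p = tmp_path / "ev.gtf"
    p.write_text(line)
    (parsed,), errors = sw.parse_astalavista(p, ann)
    assert errors == []
    assert parsed.junctions_inclusion == native.junctions_inclusion
    assert parsed.junctions_exclusion == native.junctions_exclusion


def test_parse_astalavista_error_records(tmp_path):
    ann = _cassette_annotation()
    p = tmp_path / "ev.gtf"
    p.write_text(
        _asta_line("c", "+", "g", "100^,401-", "0,??", ",201-300^", "tE,tI")
        + _asta_line("c", "+", "g", "100^,401-", "0,1-2^", ",201-300^", "tE,nosuch")
    )
    events, errors = sw.parse_astalavista(p, ann)
    assert events == []
    assert len(errors) == 2


def test_parse_astalavista_empty_file(tmp_path):
    p = tmp_path / "ev.gtf"
    p.write_text("")
    assert sw.parse_astalavista(p, _cassette_annotation()) == ([], [])
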