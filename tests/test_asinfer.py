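"""AS-event inference rules and event classification."""

from __future__ import annotations

import itertools
import random

from asgraph.asinfer import (
    classify_events,
    find_events,
    run_inference,
    summarize_events,
)
from asgraph.coords_io import GenomicInterval
from asgraph.depth import DepthCluster
from asgraph.graphmodel import ExonNode, SpliceGraph

from conftest import make_graph, make_junction


def _cluster(start, end, strand="+", depth=5):
    return DepthCluster(GenomicInterval("chr1", start, end, strand), depth)


# ---------------------------------------------------------------------------
# intron retention


def test_ir_full_intron_coverage_resolved():
    g = make_graph("g1", [(0, 100), (200, 300)], [(0, 1)])
    out, events = run_inference(g, [_cluster(50, 250)], [])
    assert (0, 300) in out.nodes
    (ev,) = events
    assert ev.type == "IR" and ev.resolved
    assert ev.introns == ((100, 200),)
    assert classify_events(out)["IR"] == 1


def test_ir_two_successive_introns_unresolved():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (400, 500)], [(0, 1), (1, 2)]
    )
    out, events = run_inference(g, [_cluster(50, 450)], [])
    (ev,) = events
    assert ev.type == "IR" and not ev.resolved
    assert out.nodes[(50, 450)].unresolved
    # unresolved nodes never gain edges and never produce typed events
    assert all((50, 450) not in e for e in out.edges)
    assert classify_events(out)["IR"] == 0


def test_ir_ambiguous_upstream_acceptors_unresolved():
    # two upstream exons with different acceptor sites overlap the cluster
    g = make_graph(
        "g1", [(0, 100), (20, 100), (200, 300)], [(0, 2), (1, 2)]
    )
    out, events = run_inference(g, [_cluster(50, 250)], [])
    (ev,) = events
    assert ev.type == "IR" and not ev.resolved


def test_ir_junction_inside_exon_splits_it():
    g = make_graph("g1", [(0, 300), (400, 500)], [(0, 1)])
    j = make_junction((120, 180), donor_origin="predicted", acceptor_origin="predicted")
    out, events = run_inference(g, [], [j])
    assert (0, 120) in out.nodes and (180, 300) in out.nodes
    assert ((0, 120), (180, 300)) in out.edges
    (ev,) = events
    assert ev.type == "IR" and ev.resolved
    assert (0, 300) in ev.nodes


def test_ir_minus_strand_coverage():
    g = make_graph("g1", [(0, 100), (200, 300)], [(1, 0)], strand="-")
    out, events = run_inference(g, [_cluster(50, 250, "-")], [])
    (ev,) = events
    assert ev.type == "IR" and ev.resolved
    assert (0, 300) in out.nodes


# ---------------------------------------------------------------------------
# alternative 3'/5'


def test_alt3_nearest_acceptor_chosen():
    g = make_graph("g1", [(0, 100), (200, 300)], [(0, 1)])
    j170 = make_junction((100, 170), acceptor_origin="predicted", support=2)
    j185 = make_junction((100, 185), acceptor_origin="predicted", support=4)
    out, events = run_inference(g, [_cluster(180, 260)], [j170, j185])
    (ev,) = events
    assert ev.type == "Alt3" and ev.resolved
    assert (185, 300) in out.nodes
    assert ((0, 100), (185, 300)) in out.edges
    assert classify_events(out)["Alt3"] == 1


def test_alt3_no_acceptor_in_intron_unresolved():
    g = make_graph("g1", [(0, 100), (200, 300)], [(0, 1)])
    out, events = run_inference(g, [_cluster(180, 260)], [])
    (ev,) = events
    assert ev.type == "Alt3" and not ev.resolved
    assert out.nodes[(180, 260)].unresolved


def test_alt3_shared_donor_resolves_across_overlapping_exons():
    # two downstream exons share donor 300
    g = make_graph(
        "g1", [(0, 100), (200, 300), (240, 300)], [(0, 1), (0, 2)]
    )
    j = make_junction((100, 185), acceptor_origin="predicted")
    out, events = run_inference(g, [_cluster(180, 260)], [j])
    (ev,) = events
    assert ev.resolved and (185, 300) in out.nodes


def test_alt5_donor_extension():
    g = make_graph("g1", [(0, 100), (200, 300)], [(0, 1)])
    j = make_junction((130, 200), donor_origin="predicted")
    out, events = run_inference(g, [_cluster(40, 125)], [j])
    (ev,) = events
    assert ev.type == "Alt5" and ev.resolved
    assert (0, 130) in out.nodes
    assert ((0, 130), (200, 300)) in out.edges


def test_alt5_minus_strand_is_extension_at_low_coordinates():
    # minus strand: donor end of exon [200,300) is 200; extension goes below it
    g = make_graph("g1", [(0, 100), (200, 300)], [(1, 0)], strand="-")
    j = make_junction((100, 170), strand="-", donor_origin="predicted")
    out, events = run_inference(g, [_cluster(175, 260, "-")], [j])
    (ev,) = events
    assert ev.type == "Alt5" and ev.resolved
    assert (170, 300) in out.nodes


# ---------------------------------------------------------------------------
# exon skipping


def test_es_spanning_junction():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (400, 500)], [(0, 1), (1, 2)]
    )
    j = make_junction((100, 400))  # E1 donor to E3 acceptor, spans E2
    out, events = run_inference(g, [], [j])
    (ev,) = events
    assert ev.type == "ES" and ev.resolved
    assert ev.nodes == ((200, 300),)
    assert ((0, 100), (400, 500)) in out.edges
    assert classify_events(out)["ES"] == 1


def test_es_intronic_exon_from_flanking_junctions():
    g = make_graph("g1", [(0, 100), (400, 500)], [(0, 1)])
    jl = make_junction((100, 200), acceptor_origin="predicted")
    jr = make_junction((300, 400), donor_origin="predicted")
    out, events = run_inference(g, [_cluster(200, 300)], [jl, jr])
    (ev,) = events
    assert ev.type == "ES" and ev.resolved
    assert (200, 300) in out.nodes
    assert ((0, 100), (200, 300)) in out.edges
    assert ((200, 300), (400, 500)) in out.edges


def test_es_unassociated_flanking_junction_unresolved():
    g = make_graph("g1", [(0, 100), (400, 500)], [(0, 1)])
    # left junction donor 130 matches no exon donor in the graph
    jl = make_junction((130, 200), donor_origin="predicted", acceptor_origin="predicted")
    jr = make_junction((300, 400), donor_origin="predicted")
    out, events = run_inference(g, [_cluster(200, 300)], [jl, jr])
    (ev,) = events
    assert ev.type == "ES" and not ev.resolved
    assert out.nodes[(200, 300)].unresolved


def test_intronic_cluster_without_junctions_annotated_unresolved():
    g = make_graph("g1", [(0, 100), (400, 500)], [(0, 1)])
    out, events = run_inference(g, [_cluster(200, 300)], [])
    (ev,) = events
    assert ev.type == "ES" and not ev.resolved
    assert out.nodes[(200, 300)].unresolved
    assert summarize_events(events)["unresolved"] == 1


# ---------------------------------------------------------------------------
# pipeline-level behaviour


def test_no_evidence_leaves_graph_unchanged():
    g = make_graph("g1", [(0, 100), (200, 300)], [(0, 1)])
    out, events = run_inference(g, [], [])
    assert out == g and events == []


def test_ir_and_alt3_in_one_gene():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (400, 500)], [(0, 1), (1, 2)]
    )
    j = make_junction((300, 370), acceptor_origin="predicted")
    out, events = run_inference(
        g, [_cluster(50, 250), _cluster(365, 460)], [j]
    )
    types = sorted(ev.type for ev in events)
    assert types == ["Alt3", "IR"]
    assert all(ev.resolved for ev in events)


def test_evidence_not_reused_between_rules():
    # a junction consumed by IR scenario B cannot also fire exon skipping
    g = make_graph("g1", [(0, 300), (400, 500)], [(0, 1)])
    j = make_junction((120, 180), donor_origin="predicted", acceptor_origin="predicted")
    out, events = run_inference(g, [], [j])
    assert [ev.type for ev in events] == ["IR"]


def test_baseline_preserved_through_inference():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (400, 500)], [(0, 1), (1, 2)]
    )
    out, _ = run_inference(
        g,
        [_cluster(50, 250), _cluster(420, 480)],
        [make_junction((100, 400))],
    )
    assert set(g.nodes) <= set(out.nodes)
    assert g.edges <= out.edges


# ---------------------------------------------------------------------------
# classification predicates


def test_classify_alt3_shared_donor():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (220, 300)], [(0, 1), (0, 2)]
    )
    counts = classify_events(g)
    assert counts == {"IR": 0, "ES": 0, "Alt5": 0, "Alt3": 1}


def test_classify_alt5_shared_acceptor():
    g = make_graph(
        "g1", [(0, 80), (0, 100), (200, 300)], [(0, 2), (1, 2)]
    )
    counts = classify_events(g)
    assert counts == {"IR": 0, "ES": 0, "Alt5": 1, "Alt3": 0}


def test_classify_ir_node_over_intron():
    g = make_graph(
        "g1", [(0, 100), (200, 300), (0, 300)], [(0, 1)]
    )
    assert classify_events(g)["IR"] == 1


def test_classify_minus_strand_event_naming_flips():
    # same geometry as the Alt3 case above but on the minus strand:
    # the varying boundary is now the donor, so the event is Alt5
    g = make_graph(
        "g1", [(0, 100), (200, 300), (220, 300)], [(1, 0), (2, 0)], strand="-"
    )
    counts = classify_events(g)
    assert counts == {"IR": 0, "ES": 0, "Alt5": 1, "Alt3": 0}


def _oracle_events(g):
    """Independent brute-force scan over all node/edge combinations."""
    found = set()
    nodes = {k: n for k, n in g.nodes.items() if not n.unresolved}
    introns = {}
    for e in g.edges:
        i = g.intron(e)
        introns[e] = (i.start, i.end)
    for k in nodes:
        for e, (s, t) in introns.items():
            if k in e:
                continue
            if k[0] < s and t < k[1]:
                found.add(("IR", s, t))
    for e, (s, t) in introns.items():
        for k in nodes:
            if k in e:
                continue
            if s <= k[0] and k[1] <= t:
                has_in = any(e2[1] == k for e2 in g.edges)
                has_out = any(e2[0] == k for e2 in g.edges)
                if has_in and has_out:
                    found.add(("ES", s, t, k[0], k[1]))
    for e1, e2 in itertools.combinations(sorted(introns), 2):
        (s1, t1), (s2, t2) = introns[e1], introns[e2]
        if (s1, t1) == (s2, t2):
            continue
        d1, a1 = (s1, t1) if g.strand == "+" else (t1, s1)
        d2, a2 = (s2, t2) if g.strand == "+" else (t2, s2)
        if d1 == d2 and a1 != a2:
            found.add(("Alt3", d1, min(a1, a2), max(a1, a2)))
        if a1 == a2 and d1 != d2:
            found.add(("Alt5", a1, min(d1, d2), max(d1, d2)))
    return found


def _random_graph(rng):
    strand = rng.choice("+-")
    n_nodes = rng.randint(2, 6)
    starts = sorted(rng.sample(range(0, 80), n_nodes))
    nodes = []
    for s in starts:
        nodes.append((s * 10, s * 10 + rng.randint(3, 25) * 4))
    g = SpliceGraph("g", GenomicInterval("chr1", 0, 2000, strand), strand)
    for s, e in nodes:
        g.add_node(ExonNode(GenomicInterval("chr1", s, e, strand)))
    keys = list(g.nodes)
    for u, v in itertools.combinations(keys, 2):
        if rng.random() < 0.5:
            uu, vv = (u, v) if strand == "+" else (v, u)
            if g.edge_valid(uu, vv):
                g.add_edge(uu, vv)
    return g


def test_find_events_matches_bruteforce_on_random_graphs():
    rng = random.Random(12)
    for _ in range(200):
        g = _random_graph(rng)
        got = set()
        for ev in find_events(g):
            if ev.type == "IR":
                got.add(("IR", *ev.introns[0]))
            elif ev.type == "ES":
                got.add(("ES", *ev.introns[0], *ev.nodes[0]))
            else:
                i1, i2 = ev.introns
                d1, a1 = i1 if g.strand == "+" else i1[::-1]
                d2, a2 = i2 if g.strand == "+" else i2[::-1]
                if ev.type == "Alt3":
                    got.add(("Alt3", d1, min(a1, a2), max(a1, a2)))
                else:
                    got.add(("Alt5", a1, min(d1, d2), max(d1, d2)))
        assert got == _oracle_events(g)
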