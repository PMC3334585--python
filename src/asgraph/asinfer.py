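"""Inference of alternative-splicing events from coverage clusters and junctions.

Rules run in a fixed order — intron retention, then alternative 3'/5' sites,
then exon skipping — and evidence consumed by an earlier rule is never reused
by a later one.  Whenever the evidence does not single out one isoform the
short-read exon is annotated *unresolved*: unresolved nodes are recorded in
the graph but never receive edges and never produce typed events.

Event naming is strand-aware: variation at the donor boundary of an intron is
an alternative 5' event, variation at the acceptor boundary an alternative 3'
event, matching transcript orientation rather than genomic orientation.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

from .coords_io import GenomicInterval
from .depth import DepthCluster
from .graphmodel import ExonNode, SpliceGraph, assemble_edges
from .junctions import Junction

log = logging.getLogger(__name__)

EVENT_TYPES = ("IR", "ES", "Alt5", "Alt3")


@dataclass(frozen=True)
class ASEvent:
    """A typed alternative-splicing event and the graph elements evidencing it."""

    type: str  # "IR" | "ES" | "Alt5" | "Alt3"
    resolved: bool
    gene_id: str
    nodes: tuple[tuple[int, int], ...] = ()
    introns: tuple[tuple[int, int], ...] = ()
    evidence: tuple[tuple[str, str], ...] = ()

    def evidence_dict(self) -> dict[str, str]:
        return dict(self.evidence)


def _ev(**kwargs) -> tuple[tuple[str, str], ...]:
    return tuple((k, str(v)) for k, v in kwargs.items())


# ---------------------------------------------------------------------------
# shared helpers


def _add_unresolved(g: SpliceGraph, interval: GenomicInterval) -> ExonNode | None:
    key = (interval.start, interval.end)
    if key in g.nodes:
        return None
    node = ExonNode(
        interval, acceptor_bounded=False, donor_bounded=False,
        provenance="short_read", unresolved=True,
    )
    g.nodes[key] = node
    return node


def _junction_edges(g: SpliceGraph, j: Junction) -> int:
    """Insert every valid intron edge implied by a junction: from each exon
    ending at its donor site to each exon starting at its acceptor site."""
    donors = [k for k, n in g.nodes.items()
              if not n.unresolved and n.donor_bounded and g.donor_of(n) == j.donor.boundary]
    acceptors = [k for k, n in g.nodes.items()
                 if not n.unresolved and n.acceptor_bounded
                 and g.acceptor_of(n) == j.acceptor.boundary]
    added = 0
    for u in donors:
        for v in acceptors:
            if (u, v) not in g.edges and g.edge_valid(u, v):
                g.add_edge(u, v)
                added += 1
    return added


def _edge_intron_keys(g: SpliceGraph) -> set[tuple[int, int]]:
    return {(i.start, i.end) for i in (g.intron(e) for e in g.edges)}


def _resolve_span(
    g: SpliceGraph, span: GenomicInterval, intron: GenomicInterval
) -> GenomicInterval | None:
    """Boundaries for an exon spanning ``intron``, from the exons overlapping
    ``span`` on either side.

    All exons overlapping the forward-left side must share their left
    boundary and those on the forward-right side their right boundary; on
    either strand these are exactly the acceptor-of-upstream-exon and
    donor-of-downstream-exon coordinates.  Returns None when a boundary is
    ambiguous or a side has no overlapping exon.
    """
    left = [
        n for n in g.nodes.values()
        if not n.unresolved
        and n.interval.overlaps(span)
        and n.interval.start < intron.start
        and not (n.interval.start < intron.start and intron.end < n.interval.end)
    ]
    right = [
        n for n in g.nodes.values()
        if not n.unresolved
        and n.interval.overlaps(span)
        and n.interval.end > intron.end
        and not (n.interval.start < intron.start and intron.end < n.interval.end)
    ]
    if not left or not right:
        return None
    starts = {n.interval.start for n in left}
    ends = {n.interval.end for n in right}
    if len(starts) != 1 or len(ends) != 1:
        return None
    return GenomicInterval(span.chrom, starts.pop(), ends.pop(), g.strand)


# ---------------------------------------------------------------------------
# intron retention


def infer_intron_retention(
    g: SpliceGraph,
    clusters: Sequence[DepthCluster],
    junctions: Sequence[Junction],
    consumed_clusters: set[int],
    consumed_junctions: set[tuple],
) -> list[ASEvent]:
    """Two IR scenarios.

    Coverage scenario: a cluster spanning an intron's full length evidences
    retention of that intron; the retained exon's boundaries come from the
    exons overlapping either end and must be unambiguous.  A cluster spanning
    two or more distinct introns cannot be attributed to a single retention
    and is annotated unresolved.

    Junction scenario: an accepted novel junction strictly inside a known
    exon evidences an intron excised from that exon in some transcripts; two
    flanking sub-exons are created, the known exon being the retained form.
    """
    events: list[ASEvent] = []
    existing_introns = _edge_intron_keys(g)
    new_nodes: list[ExonNode] = []
    for idx, c in enumerate(clusters):
        covered = sorted(
            {
                (i.start, i.end)
                for i in (g.intron(e) for e in g.edges)
                if c.interval.contains(i)
            }
        )
        if not covered:
            continue
        consumed_clusters.add(idx)
        if len(covered) >= 2:
            node = _add_unresolved(g, c.interval)
            events.append(
                ASEvent(
                    "IR", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    introns=tuple(covered),
                    evidence=_ev(reason="multi_intron_coverage", min_depth=c.min_depth),
                )
            )
            continue
        intron = GenomicInterval(c.interval.chrom, covered[0][0], covered[0][1], g.strand)
        span = _resolve_span(g, c.interval, intron)
        if span is None:
            node = _add_unresolved(g, c.interval)
            events.append(
                ASEvent(
                    "IR", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    introns=(covered[0],),
                    evidence=_ev(reason="ambiguous_boundary", min_depth=c.min_depth),
                )
            )
            continue
        key = (span.start, span.end)
        if key not in g.nodes:
            node = ExonNode(span, True, True, provenance="short_read")
            g.add_node(node)
            new_nodes.append(node)
        events.append(
            ASEvent(
                "IR", True, g.gene_id,
                nodes=(key,),
                introns=(covered[0],),
                evidence=_ev(scenario="coverage", min_depth=c.min_depth),
            )
        )
    for j in junctions:
        if j.key in consumed_junctions:
            continue
        ji = j.intron
        if (ji.start, ji.end) in existing_introns:
            continue
        containers = [
            n for n in g.nodes.values()
            if not n.unresolved
            and n.interval.start < ji.start
            and ji.end < n.interval.end
        ]
        if not containers:
            continue
        consumed_junctions.add(j.key)
        starts = {n.interval.start for n in containers}
        ends = {n.interval.end for n in containers}
        if len(starts) != 1 or len(ends) != 1:
            union = GenomicInterval(
                ji.chrom, min(starts), max(ends), g.strand
            )
            node = _add_unresolved(g, union)
            events.append(
                ASEvent(
                    "IR", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    introns=((ji.start, ji.end),),
                    evidence=_ev(reason="ambiguous_boundary", junction_support=j.support),
                )
            )
            continue
        s, e = starts.pop(), ends.pop()
        left = ExonNode(
            GenomicInterval(ji.chrom, s, ji.start, g.strand),
            True, True, provenance="inferred",
        )
        right = ExonNode(
            GenomicInterval(ji.chrom, ji.end, e, g.strand),
            True, True, provenance="inferred",
        )
        for node in (left, right):
            if node.key not in g.nodes:
                g.add_node(node)
                new_nodes.append(node)
        u, v = (left.key, right.key) if g.strand == "+" else (right.key, left.key)
        if (u, v) not in g.edges and g.edge_valid(u, v):
            g.add_edge(u, v)
        events.append(
            ASEvent(
                "IR", True, g.gene_id,
                nodes=(containers[0].key, left.key, right.key),
                introns=((ji.start, ji.end),),
                evidence=_ev(scenario="junction_in_exon", junction_support=j.support),
            )
        )
    if new_nodes:
        assemble_edges(g, new_nodes)
    return events


# ---------------------------------------------------------------------------
# alternative 3' / 5' sites


def _nearest(boundaries: Iterable[int], ref: int) -> int:
    return min(boundaries, key=lambda b: (abs(b - ref), b))


def infer_alt_site(
    g: SpliceGraph,
    short_read_exons: Sequence[ExonNode],
    junctions: Sequence[Junction],
    consumed_sr: set[int],
    consumed_junctions: set[tuple],
) -> list[ASEvent]:
    """Alternative acceptor (3') and donor (5') inference.

    Both forms of evidence are required: a short-read exon overlapping an
    existing exon and extending into its flanking intron, and an accepted
    junction with a site inside that intron.  The junction site nearest the
    short-read exon gives the new boundary; the opposite end resolves only if
    every overlapping exon on that side shares the same site.
    """
    events: list[ASEvent] = []
    new_nodes: list[ExonNode] = []
    for idx, sr in enumerate(short_read_exons):
        if idx in consumed_sr:
            continue
        si = sr.interval
        overlapped = [
            n for n in g.nodes.values()
            if not n.unresolved and n.interval.overlaps(si)
        ]
        if not overlapped:
            continue  # intronic candidates belong to exon-skipping inference
        consumed_sr.add(idx)
        handled = False
        for n in sorted(overlapped, key=lambda n: n.key):
            # extension past the acceptor (5') end -> alternative acceptor (3' event)
            ext_acc = (
                si.start < n.interval.start if g.strand == "+" else si.end > n.interval.end
            )
            if ext_acc and n.acceptor_bounded:
                ev = _alt_one_side(
                    g, si, n, junctions, consumed_junctions, side="acceptor",
                )
                if ev is not None:
                    events.append(ev)
                    if ev.resolved and ev.nodes:
                        node = g.nodes.get(ev.nodes[0])
                        if node is not None:
                            new_nodes.append(node)
                    handled = True
                    break
            ext_don = (
                si.end > n.interval.end if g.strand == "+" else si.start < n.interval.start
            )
            if ext_don and n.donor_bounded:
                ev = _alt_one_side(
                    g, si, n, junctions, consumed_junctions, side="donor",
                )
                if ev is not None:
                    events.append(ev)
                    if ev.resolved and ev.nodes:
                        node = g.nodes.get(ev.nodes[0])
                        if node is not None:
                            new_nodes.append(node)
                    handled = True
                    break
        if not handled:
            continue
    if new_nodes:
        assemble_edges(g, new_nodes)
    return events


def _alt_one_side(
    g: SpliceGraph,
    si: GenomicInterval,
    n: ExonNode,
    junctions: Sequence[Junction],
    consumed_junctions: set[tuple],
    side: str,
) -> ASEvent | None:
    """One alternative-site inference at the acceptor or donor end of ``n``."""
    etype = "Alt3" if side == "acceptor" else "Alt5"
    if side == "acceptor":
        flank_introns = [g.intron(e) for e in g.in_edges(n.key)]
    else:
        flank_introns = [g.intron(e) for e in g.out_edges(n.key)]
    if not flank_introns:
        return None  # no flanking intron to extend into (terminal exon)
    candidates: dict[int, Junction] = {}
    for j in junctions:
        if j.key in consumed_junctions:
            continue
        boundary = j.acceptor.boundary if side == "acceptor" else j.donor.boundary
        for intron in flank_introns:
            if intron.start < boundary < intron.end:
                prev = candidates.get(boundary)
                if prev is None or j.support > prev.support:
                    candidates[boundary] = j
    # the reference point is the short-read exon end facing the intron
    if side == "acceptor":
        ref = si.start if g.strand == "+" else si.end
    else:
        ref = si.end if g.strand == "+" else si.start
    if not candidates:
        node = _add_unresolved(g, si)
        return ASEvent(
            etype, False, g.gene_id,
            nodes=(node.key,) if node else (),
            evidence=_ev(reason="no_site_in_intron"),
        )
    boundary = _nearest(candidates, ref)
    j = candidates[boundary]
    # resolve the opposite end from the exons overlapping the short-read exon
    if side == "acceptor":
        if g.strand == "+":
            others = {m.interval.end for m in g.nodes.values()
                      if not m.unresolved and m.donor_bounded
                      and m.interval.overlaps(si) and m.interval.end > boundary}
        else:
            others = {m.interval.start for m in g.nodes.values()
                      if not m.unresolved and m.donor_bounded
                      and m.interval.overlaps(si) and m.interval.start < boundary}
    else:
        if g.strand == "+":
            others = {m.interval.start for m in g.nodes.values()
                      if not m.unresolved and m.acceptor_bounded
                      and m.interval.overlaps(si) and m.interval.start < boundary}
        else:
            others = {m.interval.end for m in g.nodes.values()
                      if not m.unresolved and m.acceptor_bounded
                      and m.interval.overlaps(si) and m.interval.end > boundary}
    if len(others) != 1:
        node = _add_unresolved(g, si)
        return ASEvent(
            etype, False, g.gene_id,
            nodes=(node.key,) if node else (),
            evidence=_ev(reason="ambiguous_boundary"),
        )
    other = others.pop()
    start, end = min(boundary, other), max(boundary, other)
    interval = GenomicInterval(si.chrom, start, end, g.strand)
    key = (start, end)
    consumed_junctions.add(j.key)
    if key not in g.nodes:
        node = ExonNode(interval, True, True, provenance="short_read")
        g.add_node(node)
        _junction_edges(g, j)
    return ASEvent(
        etype, True, g.gene_id,
        nodes=(key,),
        introns=((j.intron.start, j.intron.end),),
        evidence=_ev(junction_support=j.support),
    )


# ---------------------------------------------------------------------------
# exon skipping


def infer_exon_skipping(
    g: SpliceGraph,
    short_read_exons: Sequence[ExonNode],
    junctions: Sequence[Junction],
    consumed_sr: set[int],
    consumed_junctions: set[tuple],
) -> list[ASEvent]:
    """Two ES scenarios.

    Spanning-junction scenario: a novel junction whose donor and acceptor
    match established exons and whose intron contains at least one existing
    exon evidences skipping of the contained exon(s).

    Intronic-exon scenario: a short-read exon inside an intron, flanked by
    two novel junctions whose outer sites associate with graph exons, is a
    novel exon skipped in the constitutive form; its boundaries are the
    flanking junctions' inner sites.  Association failure leaves the
    short-read exon unresolved.
    """
    events: list[ASEvent] = []
    new_nodes: list[ExonNode] = []
    for j in junctions:
        if j.key in consumed_junctions:
            continue
        ji = j.intron
        if (ji.start, ji.end) in _edge_intron_keys(g):
            continue
        donor_match = any(
            not n.unresolved and n.donor_bounded and g.donor_of(n) == j.donor.boundary
            for n in g.nodes.values()
        )
        acceptor_match = any(
            not n.unresolved and n.acceptor_bounded
            and g.acceptor_of(n) == j.acceptor.boundary
            for n in g.nodes.values()
        )
        if not (donor_match and acceptor_match):
            continue
        skipped = [
            n for n in g.nodes.values()
            if not n.unresolved
            and ji.start <= n.interval.start
            and n.interval.end <= ji.end
        ]
        if not skipped:
            continue
        consumed_junctions.add(j.key)
        _junction_edges(g, j)
        for n in skipped:
            events.append(
                ASEvent(
                    "ES", True, g.gene_id,
                    nodes=(n.key,),
                    introns=((ji.start, ji.end),),
                    evidence=_ev(scenario="spanning_junction", junction_support=j.support),
                )
            )
    for idx, sr in enumerate(short_read_exons):
        if idx in consumed_sr:
            continue
        si = sr.interval
        if any(
            not n.unresolved and n.interval.overlaps(si) for n in g.nodes.values()
        ):
            continue
        left_candidates = [
            j for j in junctions
            if j.key not in consumed_junctions
            and j.intron.start < si.start
            and j.intron.end <= si.end
        ]
        right_candidates = [
            j for j in junctions
            if j.key not in consumed_junctions
            and j.intron.end > si.end
            and j.intron.start >= si.start
        ]
        consumed_sr.add(idx)
        if not left_candidates or not right_candidates:
            node = _add_unresolved(g, si)
            events.append(
                ASEvent(
                    "ES", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    evidence=_ev(reason="missing_flanking_junction"),
                )
            )
            continue
        jl = min(left_candidates, key=lambda j: abs(j.intron.end - si.start))
        jr = min(right_candidates, key=lambda j: abs(j.intron.start - si.end))
        if jl.intron.end >= jr.intron.start:
            node = _add_unresolved(g, si)
            events.append(
                ASEvent(
                    "ES", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    evidence=_ev(reason="inconsistent_flanking_junctions"),
                )
            )
            continue
        # outer sites must associate with exons already in the graph
        associated = True
        for j, outer_boundary in ((jl, jl.intron.start), (jr, jr.intron.end)):
            role = (
                j.donor.role if j.donor.boundary == outer_boundary else j.acceptor.role
            )
            if role == "donor":
                ok = any(
                    not n.unresolved and n.donor_bounded
                    and g.donor_of(n) == outer_boundary
                    for n in g.nodes.values()
                )
            else:
                ok = any(
                    not n.unresolved and n.acceptor_bounded
                    and g.acceptor_of(n) == outer_boundary
                    for n in g.nodes.values()
                )
            associated = associated and ok
        if not associated:
            node = _add_unresolved(g, si)
            events.append(
                ASEvent(
                    "ES", False, g.gene_id,
                    nodes=(node.key,) if node else (),
                    evidence=_ev(reason="unassociated_flanking_junction"),
                )
            )
            continue
        interval = GenomicInterval(si.chrom, jl.intron.end, jr.intron.start, g.strand)
        key = (interval.start, interval.end)
        consumed_junctions.add(jl.key)
        consumed_junctions.add(jr.key)
        if key not in g.nodes:
            node = ExonNode(interval, True, True, provenance="short_read")
            g.add_node(node)
            new_nodes.append(node)
            _junction_edges(g, jl)
            _junction_edges(g, jr)
        events.append(
            ASEvent(
                "ES", True, g.gene_id,
                nodes=(key,),
                introns=(
                    (jl.intron.start, jl.intron.end),
                    (jr.intron.start, jr.intron.end),
                ),
                evidence=_ev(
                    scenario="intronic_exon",
                    junction_support=jl.support + jr.support,
                ),
            )
        )
    if new_nodes:
        assemble_edges(g, new_nodes)
    return events


# ---------------------------------------------------------------------------
# driver


def run_inference(
    g: SpliceGraph,
    clusters: Sequence[DepthCluster],
    junctions: Sequence[Junction],
    depth_threshold: int = 0,
) -> tuple[SpliceGraph, list[ASEvent]]:
    """Apply the inference rules in order and complete edge assembly.

    Input graph is left untouched; evidence consumed by one rule is not
    reused by later ones.  Baseline nodes and edges are always preserved.
    """
    g = g.copy()
    events: list[ASEvent] = []
    consumed_clusters: set[int] = set()
    consumed_junctions: set[tuple] = set()
    events += infer_intron_retention(
        g, clusters, junctions, consumed_clusters, consumed_junctions
    )
    sr_exons: list[ExonNode] = []
    for idx, c in enumerate(clusters):
        if idx in consumed_clusters:
            continue
        if any(n.interval.contains(c.interval) for n in g.nodes.values()):
            continue
        sr_exons.append(
            ExonNode(c.interval, False, False, provenance="short_read")
        )
    consumed_sr: set[int] = set()
    events += infer_alt_site(g, sr_exons, junctions, consumed_sr, consumed_junctions)
    events += infer_exon_skipping(g, sr_exons, junctions, consumed_sr, consumed_junctions)
    for idx, sr in enumerate(sr_exons):
        if idx in consumed_sr:
            continue
        _add_unresolved(g, sr.interval)
    return g, events


# ---------------------------------------------------------------------------
# event classification on arbitrary graphs


def find_events(g: SpliceGraph) -> list[ASEvent]:
    """Scan a graph for AS events, de-duplicated by the splice sites involved.

    Predicates: IR — a node strictly containing an intron edge between two
    other nodes; ES — an intron edge containing a node that has both an
    incoming and an outgoing edge; Alt5/Alt3 — two intron edges sharing one
    boundary (acceptor for Alt5, donor for Alt3, in transcript orientation)
    and differing at the other.
    """
    events: list[ASEvent] = []
    seen: set[tuple] = set()
    edges = sorted(g.edges)
    for key, n in sorted(g.nodes.items()):
        if n.unresolved:
            continue
        for e in edges:
            u, v = e
            if key in (u, v):
                continue
            i = g.intron(e)
            if n.interval.start < i.start and i.end < n.interval.end:
                sig = ("IR", i.start, i.end)
                if sig not in seen:
                    seen.add(sig)
                    events.append(
                        ASEvent("IR", True, g.gene_id, nodes=(key,),
                                introns=((i.start, i.end),))
                    )
    for e in edges:
        u, v = e
        i = g.intron(e)
        for key, n in sorted(g.nodes.items()):
            if n.unresolved or key in (u, v):
                continue
            if i.start <= n.interval.start and n.interval.end <= i.end:
                if g.in_edges(key) and g.out_edges(key):
                    sig = ("ES", i.start, i.end, key[0], key[1])
                    if sig not in seen:
                        seen.add(sig)
                        events.append(
                            ASEvent("ES", True, g.gene_id, nodes=(key,),
                                    introns=((i.start, i.end),))
                        )
    for a in range(len(edges)):
        for b in range(a + 1, len(edges)):
            d1, a1 = g.intron_sites(edges[a])
            d2, a2 = g.intron_sites(edges[b])
            if (d1, a1) == (d2, a2):
                continue
            if d1 == d2 and a1 != a2:
                sig = ("Alt3", d1, min(a1, a2), max(a1, a2))
                etype = "Alt3"
            elif a1 == a2 and d1 != d2:
                sig = ("Alt5", a1, min(d1, d2), max(d1, d2))
                etype = "Alt5"
            else:
                continue
            if sig in seen:
                continue
            seen.add(sig)
            i1, i2 = g.intron(edges[a]), g.intron(edges[b])
            events.append(
                ASEvent(etype, True, g.gene_id,
                        introns=((i1.start, i1.end), (i2.start, i2.end)))
            )
    return events


def classify_events(g: SpliceGraph) -> dict[str, int]:
    """Counts of AS events by type in one graph."""
    counts = {t: 0 for t in EVENT_TYPES}
    for ev in find_events(g):
        counts[ev.type] += 1
    return counts


# ---------------------------------------------------------------------------
# reports


def write_event_table(events: Iterable[ASEvent], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        fh.write("gene\ttype\tresolved\tnodes\tintrons\tevidence\n")
        for ev in events:
            nodes = ",".join(f"{s}-{e}" for s, e in ev.nodes) or "."
            introns = ",".join(f"{s}-{e}" for s, e in ev.introns) or "."
            evidence = ";".join(f"{k}={v}" for k, v in ev.evidence) or "."
            fh.write(
                f"{ev.gene_id}\t{ev.type}\t{int(ev.resolved)}\t{nodes}\t{introns}\t{evidence}\n"
            )
            n += 1
    return n


def summarize_events(events: Iterable[ASEvent]) -> dict[str, int]:
    """Per-type counts of resolved events plus the unresolved annotation count."""
    counts = Counter()
    for ev in events:
        if ev.resolved:
            counts[ev.type] += 1
        else:
            counts["unresolved"] += 1
    return {t: counts.get(t, 0) for t in (*EVENT_TYPES, "unresolved")}


def graph_summary(g: SpliceGraph) -> str:
    """Plain-text dump of a splice graph (the visualization stand-in)."""
    lines = [
        f"gene {g.gene_id} {g.interval.chrom}:{g.interval.start}-{g.interval.end}({g.strand})",
        f"  {len(g.nodes)} exons, {len(g.edges)} introns",
    ]
    for n in g.node_list():
        flags = []
        if not n.acceptor_bounded:
            flags.append("acceptor-unbounded")
        if not n.donor_bounded:
            flags.append("donor-unbounded")
        if n.unresolved:
            flags.append("UNRESOLVED")
        tag = f" [{', '.join(flags)}]" if flags else ""
        lines.append(
            f"  exon {n.interval.start}-{n.interval.end} ({n.provenance}){tag}"
        )
    for e in sorted(g.edges):
        i = g.intron(e)
        lines.append(f"  intron {i.start}-{i.end} ({e[0]}->{e[1]})")
    counts = classify_events(g)
    lines.append(
        "  events: " + ", ".join(f"{t}={counts[t]}" for t in EVENT_TYPES)
    )
    return "\n".join(lines)
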