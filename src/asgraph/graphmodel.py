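"""The splice-graph data structure and its construction/merge rules.

A splice graph represents one gene: nodes are exons, directed edges are the
introns that connect them in transcription order.  Exon ends are described in
transcript orientation: the *acceptor* end is the 5' end of the exon and the
*donor* end the 3' end, so on the minus strand the acceptor end is the higher
genomic coordinate.  An end is *bounded* when an explicit splice site defines
it and *unbounded* otherwise (typical of EST termini and coverage clusters).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from .coords_io import GeneModel, GenomicInterval, ModelError

log = logging.getLogger(__name__)

#: when two nodes have identical boundaries, the higher-priority provenance wins
PROVENANCE_PRIORITY = {"gene_model": 0, "est": 1, "short_read": 2, "inferred": 3}

NodeKey = tuple[int, int]


class GraphError(ValueError):
    """A structurally invalid graph operation."""


@dataclass
class ExonNode:
    """An exon node with boundedness flags referring to transcription-order ends."""

    interval: GenomicInterval
    acceptor_bounded: bool = True
    donor_bounded: bool = True
    provenance: str = "gene_model"
    unresolved: bool = False

    @property
    def key(self) -> NodeKey:
        return (self.interval.start, self.interval.end)

    @property
    def bounded(self) -> bool:
        return self.acceptor_bounded and self.donor_bounded


class SpliceGraph:
    """Directed graph of exons (nodes) and introns (edges) for one gene."""

    def __init__(self, gene_id: str, interval: GenomicInterval, strand: str):
        self.gene_id = gene_id
        self.interval = interval
        self.strand = strand
        self.nodes: dict[NodeKey, ExonNode] = {}
        self.edges: set[tuple[NodeKey, NodeKey]] = set()

    # -- strand-aware end coordinates ------------------------------------

    def acceptor_of(self, node: ExonNode) -> int:
        """Genomic boundary coordinate of the node's acceptor (5') end."""
        return node.interval.start if self.strand == "+" else node.interval.end

    def donor_of(self, node: ExonNode) -> int:
        """Genomic boundary coordinate of the node's donor (3') end."""
        return node.interval.end if self.strand == "+" else node.interval.start

    def is_upstream(self, a: NodeKey, b: NodeKey) -> bool:
        """True when node a precedes node b in transcription order (disjoint)."""
        if self.strand == "+":
            return a[1] <= b[0]
        return b[1] <= a[0]

    def intron(self, edge: tuple[NodeKey, NodeKey]) -> GenomicInterval:
        """Forward-axis gap implied by an (upstream, downstream) edge."""
        u, v = edge
        if self.strand == "+":
            return GenomicInterval(self.interval.chrom, u[1], v[0], self.strand)
        return GenomicInterval(self.interval.chrom, v[1], u[0], self.strand)

    def intron_sites(self, edge: tuple[NodeKey, NodeKey]) -> tuple[int, int]:
        """(donor boundary, acceptor boundary) of the edge's intron."""
        i = self.intron(edge)
        return (i.start, i.end) if self.strand == "+" else (i.end, i.start)

    # -- mutation ---------------------------------------------------------

    def add_node(self, node: ExonNode) -> ExonNode:
        """Add a node, collapsing with an identical-boundary node if present.

        On collapse the higher-priority provenance wins, boundedness flags are
        OR-combined and the node stays resolved if either copy was.
        """
        existing = self.nodes.get(node.key)
        if existing is None:
            self.nodes[node.key] = node
            return node
        merged = ExonNode(
            interval=existing.interval,
            acceptor_bounded=existing.acceptor_bounded or node.acceptor_bounded,
            donor_bounded=existing.donor_bounded or node.donor_bounded,
            provenance=min(
                existing.provenance, node.provenance,
                key=lambda p: PROVENANCE_PRIORITY.get(p, 99),
            ),
            unresolved=existing.unresolved and node.unresolved,
        )
        self.nodes[node.key] = merged
        return merged

    def edge_valid(self, u: NodeKey, v: NodeKey) -> bool:
        if u not in self.nodes or v not in self.nodes:
            return False
        if self.nodes[u].unresolved or self.nodes[v].unresolved:
            return False
        if not self.is_upstream(u, v):
            return False
        gap = v[0] - u[1] if self.strand == "+" else u[0] - v[1]
        return gap > 0

    def add_edge(self, u: NodeKey, v: NodeKey) -> None:
        """Add the intron edge u -> v (transcription order); validates structure."""
        if u not in self.nodes or v not in self.nodes:
            raise GraphError(f"edge references unknown node: {u} -> {v}")
        if self.nodes[u].unresolved or self.nodes[v].unresolved:
            raise GraphError("unresolved nodes cannot participate in edges")
        if not self.is_upstream(u, v):
            raise GraphError(f"edge {u} -> {v} not in transcription order")
        gap = v[0] - u[1] if self.strand == "+" else u[0] - v[1]
        if gap <= 0:
            raise GraphError(f"edge {u} -> {v} implies an empty intron")
        self.edges.add((u, v))

    def rekey_node(self, old: NodeKey, node: ExonNode) -> None:
        """Replace the node stored at ``old`` with ``node`` (possibly new extent)."""
        del self.nodes[old]
        self.nodes[node.key] = node
        if node.key == old:
            return
        remapped = set()
        for u, v in self.edges:
            u = node.key if u == old else u
            v = node.key if v == old else v
            remapped.add((u, v))
        self.edges = set()
        for u, v in remapped:
            if self.edge_valid(u, v):
                self.edges.add((u, v))
            else:
                log.warning(
                    "%s: dropping edge %s -> %s invalidated by node merge",
                    self.gene_id, u, v,
                )

    # -- queries ----------------------------------------------------------

    def in_edges(self, key: NodeKey) -> list[tuple[NodeKey, NodeKey]]:
        return [e for e in self.edges if e[1] == key]

    def out_edges(self, key: NodeKey) -> list[tuple[NodeKey, NodeKey]]:
        return [e for e in self.edges if e[0] == key]

    def node_list(self) -> list[ExonNode]:
        """Nodes in transcription order."""
        nodes = sorted(self.nodes.values(), key=lambda n: n.key)
        return nodes if self.strand == "+" else nodes[::-1]

    def copy(self) -> "SpliceGraph":
        g = SpliceGraph(self.gene_id, self.interval, self.strand)
        g.nodes = {k: replace(n) for k, n in self.nodes.items()}
        g.edges = set(self.edges)
        return g

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpliceGraph):
            return NotImplemented
        return (
            self.gene_id == other.gene_id
            and self.strand == other.strand
            and self.edges == other.edges
            and self.nodes.keys() == other.nodes.keys()
            and all(self.nodes[k] == other.nodes[k] for k in self.nodes)
        )

    def __repr__(self) -> str:
        return (
            f"SpliceGraph({self.gene_id}, {len(self.nodes)} nodes, "
            f"{len(self.edges)} edges)"
        )


# ---------------------------------------------------------------------------
# construction


def _check_transcript(exons: Sequence[GenomicInterval], tid: str) -> None:
    for a, b in zip(exons, exons[1:]):
        if b.start < a.end:
            raise ModelError(f"transcript {tid} has overlapping exons")


def _transcription_order(
    exons: Sequence[GenomicInterval], strand: str
) -> list[GenomicInterval]:
    ordered = sorted(exons, key=lambda e: e.start)
    return ordered if strand == "+" else ordered[::-1]


def graph_from_gene_model(m: GeneModel, provenance: str = "gene_model") -> SpliceGraph:
    """Build a splice graph directly from a gene model.

    One node is created per distinct exon interval across all transcripts and
    one edge per distinct pair of transcript-adjacent exons.  Gene models
    define their transcript ends, so every node is bounded at both ends.
    """
    strand = m.interval.strand
    g = SpliceGraph(m.gene_id, m.interval, strand)
    for tid, exons in m.transcripts:
        _check_transcript(sorted(exons, key=lambda e: e.start), tid)
        ordered = _transcription_order(exons, strand)
        for e in ordered:
            g.add_node(ExonNode(e, True, True, provenance))
        for a, b in zip(ordered, ordered[1:]):
            g.add_edge((a.start, a.end), (b.start, b.end))
    return g


def est_graph_from_transcripts(
    gene_id: str,
    interval: GenomicInterval,
    transcripts: Sequence[tuple[str, Sequence[GenomicInterval]]],
) -> SpliceGraph:
    """Build a graph from EST/cDNA transcripts with unbounded terminal exons.

    The first exon of an EST (transcription order) is unbounded at its 5'
    (acceptor) end and the last at its 3' (donor) end; an exon internal in any
    EST is bounded at that end.
    """
    strand = interval.strand
    g = SpliceGraph(gene_id, interval, strand)
    acceptor_bounded: dict[NodeKey, bool] = {}
    donor_bounded: dict[NodeKey, bool] = {}
    adjacency: list[tuple[NodeKey, NodeKey]] = []
    for tid, exons in transcripts:
        _check_transcript(sorted(exons, key=lambda e: e.start), tid)
        ordered = _transcription_order(exons, strand)
        for i, e in enumerate(ordered):
            key = (e.start, e.end)
            acc = i > 0
            don = i < len(ordered) - 1
            acceptor_bounded[key] = acceptor_bounded.get(key, False) or acc
            donor_bounded[key] = donor_bounded.get(key, False) or don
        for a, b in zip(ordered, ordered[1:]):
            adjacency.append(((a.start, a.end), (b.start, b.end)))
    for tid, exons in transcripts:
        for e in exons:
            key = (e.start, e.end)
            g.add_node(
                ExonNode(
                    e,
                    acceptor_bounded=acceptor_bounded[key],
                    donor_bounded=donor_bounded[key],
                    provenance="est",
                )
            )
    for u, v in adjacency:
        g.add_edge(u, v)
    return g


# ---------------------------------------------------------------------------
# EST merge rules


def _containment(inner: ExonNode, outer: ExonNode) -> bool:
    return outer.interval.contains(inner.interval)


def _merge_candidates_at(
    g: SpliceGraph, en: ExonNode, end: str
) -> list[ExonNode]:
    """Graph nodes sharing the splice site at ``end`` ('acceptor' or 'donor')."""
    if end == "acceptor":
        coord = g.acceptor_of(en)
        return [
            n for n in g.nodes.values()
            if n.acceptor_bounded and g.acceptor_of(n) == coord
        ]
    coord = g.donor_of(en)
    return [
        n for n in g.nodes.values()
        if n.donor_bounded and g.donor_of(n) == coord
    ]


def _resolve_merge(g: SpliceGraph, en: ExonNode) -> tuple[NodeKey, GenomicInterval] | None:
    """Find the base node an incoming exon merges into, and the merged extent.

    An exon unbounded at its 3' (donor) end merges with another exon sharing
    its acceptor site when both are unbounded at the 3' end (the merged extent
    is their union); when one is bounded, they merge only if the unbounded
    exon is contained within the bounded one.  The analogous rules apply at
    the 5' end.  An exon unbounded at both ends is absorbed by any exon that
    contains it; a fully bounded exon merges only with an identical node.
    """
    iv = en.interval
    if en.key in g.nodes:
        return en.key, iv
    if not en.acceptor_bounded and not en.donor_bounded:
        for n in g.nodes.values():
            if _containment(en, n):
                return n.key, n.interval
        return None
    shared_end = None
    if en.acceptor_bounded and not en.donor_bounded:
        shared_end = "acceptor"
    elif en.donor_bounded and not en.acceptor_bounded:
        shared_end = "donor"
    if shared_end is None:
        return None  # fully bounded, no identical node
    candidates = _merge_candidates_at(g, en, shared_end)
    free_flag = "donor_bounded" if shared_end == "acceptor" else "acceptor_bounded"
    # containment into a bounded exon takes precedence: it pins the extent
    for n in candidates:
        if getattr(n, free_flag) and _containment(en, n):
            return n.key, n.interval
    for n in candidates:
        if not getattr(n, free_flag):
            # both unbounded at the free end: merged extent is the union
            union = GenomicInterval(
                iv.chrom,
                min(iv.start, n.interval.start),
                max(iv.end, n.interval.end),
                iv.strand,
            )
            return n.key, union
    return None


def merge_est_graph(base: SpliceGraph, est: SpliceGraph) -> SpliceGraph:
    """Merge an EST-derived graph into a baseline graph.

    EST exons merge with existing exons under the bounded/unbounded rules;
    unmergeable novel exons are added as new nodes.  Introns implied by EST
    adjacency are inserted, then edge assembly completes the connectivity of
    new nodes.
    """
    if base.strand != est.strand:
        raise GraphError(
            f"strand mismatch merging {est.gene_id} into {base.gene_id}"
        )
    g = base.copy()
    mapping: dict[NodeKey, NodeKey] = {}
    new_keys: list[NodeKey] = []
    for en in est.node_list():
        resolved = _resolve_merge(g, en)
        if resolved is None:
            added = g.add_node(replace(en))
            mapping[en.key] = added.key
            new_keys.append(added.key)
            continue
        target_key, extent = resolved
        target = g.nodes[target_key]
        merged = ExonNode(
            interval=extent,
            acceptor_bounded=target.acceptor_bounded or en.acceptor_bounded,
            donor_bounded=target.donor_bounded or en.donor_bounded,
            provenance=min(
                target.provenance, en.provenance,
                key=lambda p: PROVENANCE_PRIORITY.get(p, 99),
            ),
            unresolved=target.unresolved and en.unresolved,
        )
        g.rekey_node(target_key, merged)
        mapping[en.key] = merged.key
        mapping.update(
            {k: merged.key for k, v in mapping.items() if v == target_key}
        )
        if target_key in new_keys and merged.key != target_key:
            new_keys[new_keys.index(target_key)] = merged.key
    for u, v in est.edges:
        mu, mv = mapping[u], mapping[v]
        if mu == mv:
            continue
        if g.edge_valid(mu, mv):
            g.add_edge(mu, mv)
        else:
            log.warning(
                "%s: skipping EST intron %s -> %s (invalid after merge)",
                g.gene_id, mu, mv,
            )
    assemble_edges(g, [g.nodes[k] for k in new_keys if k in g.nodes])
    return g


# ---------------------------------------------------------------------------
# edge assembly


def assemble_edges(
    g: SpliceGraph, new_nodes: Iterable[ExonNode] | None = None
) -> SpliceGraph:
    """Complete connectivity for newly added exons.

    For each new exon, incoming edges are copied from exons sharing its
    acceptor site and outgoing edges from exons sharing its donor site.  The
    copy is iterated to a fixed point so that edges gained by one new node
    propagate to others sharing a site with it.
    """
    if new_nodes is None:
        targets = {k for k, n in g.nodes.items() if not n.unresolved}
    else:
        targets = {n.key for n in new_nodes if not n.unresolved and n.key in g.nodes}
    changed = True
    while changed:
        changed = False
        for key in list(targets):
            node = g.nodes.get(key)
            if node is None or node.unresolved:
                continue
            if node.acceptor_bounded:
                coord = g.acceptor_of(node)
                for ok, other in g.nodes.items():
                    if ok == key or other.unresolved or not other.acceptor_bounded:
                        continue
                    if g.acceptor_of(other) != coord:
                        continue
                    for p, _ in g.in_edges(ok):
                        if (p, key) not in g.edges and g.edge_valid(p, key):
                            g.add_edge(p, key)
                            changed = True
            if node.donor_bounded:
                coord = g.donor_of(node)
                for ok, other in g.nodes.items():
                    if ok == key or other.unresolved or not other.donor_bounded:
                        continue
                    if g.donor_of(other) != coord:
                        continue
                    for _, s in g.out_edges(ok):
                        if (key, s) not in g.edges and g.edge_valid(key, s):
                            g.add_edge(key, s)
                            changed = True
    return g
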