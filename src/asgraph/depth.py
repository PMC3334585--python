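"""Per-base read depth within genes and short-read exon candidates.

Depth counts use accepted ungapped alignments only; the anchors of spliced
reads serve exclusively as junction evidence and do not contribute.  Clusters
are maximal runs where the depth is strictly above a threshold, so the
default threshold of 0 requires at least one covering read per base.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .coords_io import GeneModel, GenomicInterval, ReadAlignment
from .graphmodel import ExonNode, SpliceGraph

log = logging.getLogger(__name__)


@dataclass
class DepthVector:
    """Exact per-base coverage over one gene; position 0 maps to ``origin``."""

    gene_id: str
    origin: int
    counts: np.ndarray  # int32, length = gene interval length


@dataclass(frozen=True)
class DepthCluster:
    """A maximal above-threshold coverage run."""

    interval: GenomicInterval
    min_depth: int


def depth_vector(gene: GeneModel, alignments: Iterable[ReadAlignment]) -> DepthVector:
    """Tally per-base coverage of accepted alignments inside the gene.

    Bases of an alignment outside the gene interval are ignored; reads are
    assigned to every gene they overlap, so the same alignment may contribute
    to several overlapping genes.
    """
    gi = gene.interval
    counts = np.zeros(gi.length, dtype=np.int32)
    for a in alignments:
        for b in a.blocks:
            if b.chrom != gi.chrom:
                continue
            s = max(b.start, gi.start) - gi.start
            e = min(b.end, gi.end) - gi.start
            if s < e:
                counts[s:e] += 1
    return DepthVector(gene.gene_id, gi.start, counts)


def assemble_clusters(
    d: DepthVector, threshold: int = 0, chrom: str | None = None, strand: str = "+"
) -> list[DepthCluster]:
    """Maximal runs where depth is strictly above ``threshold``."""
    if threshold < 0:
        raise ValueError("depth threshold must be non-negative")
    mask = d.counts > threshold
    if not mask.any():
        return []
    padded = np.concatenate(([False], mask, [False]))
    diffs = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = diffs[0::2], diffs[1::2]
    chrom = chrom if chrom is not None else "."
    return [
        DepthCluster(
            GenomicInterval(chrom, d.origin + int(s), d.origin + int(e), strand),
            int(d.counts[s:e].min()),
        )
        for s, e in zip(starts, ends)
    ]


def _snap(
    pos: int,
    candidates: Sequence[int],
    prefer_high: bool,
    baseline_exons: Sequence[GenomicInterval],
    gene: GenomicInterval,
) -> int | None:
    """Nearest supported boundary for one cluster end.

    The search stays within the gene and never crosses an annotated exon of
    the baseline graph (a candidate is invalid if a baseline exon lies wholly
    between it and the original position).  Ties between equidistant
    candidates prefer the one that shortens the exon, as indicated by
    ``prefer_high`` (True at an exon start, False at an exon end).
    """
    best: int | None = None
    best_dist = None
    for c in candidates:
        if not (gene.start <= c <= gene.end):
            continue
        lo, hi = min(c, pos), max(c, pos)
        if any(lo < ex.start and ex.end < hi for ex in baseline_exons):
            continue
        dist = abs(c - pos)
        if best_dist is None or dist < best_dist:
            best, best_dist = c, dist
        elif dist == best_dist and best is not None:
            if (prefer_high and c > best) or (not prefer_high and c < best):
                best = c
    return best


def build_short_read_exons(
    clusters: Iterable[DepthCluster],
    graph: SpliceGraph,
    supported_sites: Iterable,
) -> list[ExonNode]:
    """Turn depth clusters into short-read exon candidates.

    Clusters contained within an existing exon are discarded.  Surviving
    cluster ends that do not already fall on a supported splice site are
    snapped to the nearest one (known sites or sites supported by accepted
    spliced reads); an end with no reachable site is left unbounded.
    """
    strand = graph.strand
    acceptors = sorted(
        s.boundary for s in supported_sites
        if s.role == "acceptor" and s.strand == strand
    )
    donors = sorted(
        s.boundary for s in supported_sites
        if s.role == "donor" and s.strand == strand
    )
    baseline = [
        n.interval for n in graph.nodes.values() if n.provenance == "gene_model"
    ]
    out: list[ExonNode] = []
    for c in clusters:
        ci = c.interval
        if any(n.interval.contains(ci) for n in graph.nodes.values()):
            continue
        # acceptor end is the exon 5' end: cluster start on +, end on -
        if strand == "+":
            acc = _snap(ci.start, acceptors, True, baseline, graph.interval)
            don = _snap(ci.end, donors, False, baseline, graph.interval)
            start = acc if acc is not None else ci.start
            end = don if don is not None else ci.end
        else:
            acc = _snap(ci.end, acceptors, False, baseline, graph.interval)
            don = _snap(ci.start, donors, True, baseline, graph.interval)
            start = don if don is not None else ci.start
            end = acc if acc is not None else ci.end
        if start >= end:
            log.warning("%s: degenerate snap for cluster %s", graph.gene_id, ci)
            continue
        out.append(
            ExonNode(
                GenomicInterval(ci.chrom, start, end, strand),
                acceptor_bounded=acc is not None,
                donor_bounded=don is not None,
                provenance="short_read",
            )
        )
    return out
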