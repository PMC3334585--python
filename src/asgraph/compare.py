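"""Recall-based comparison of predicted splice graphs against references.

Recall of a prediction set A with respect to a reference set B is
|A intersect B| / |B|, defined as 1 when B is empty.  Introns match by exact
boundary equality; exons match exactly at bounded ends, while an unbounded
end matches any extension of the corresponding reference end.  Strand
mismatches never match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .coords_io import GeneModel, GenomicInterval
from .graphmodel import ExonNode, SpliceGraph, est_graph_from_transcripts, merge_est_graph

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class RecallReport:
    exon_recall: float
    intron_recall: float
    exons_matched: int
    exons_total: int
    introns_matched: int
    introns_total: int
    novel_exons: int
    novel_introns: int


def recall(a: Iterable, b: Iterable) -> float:
    """|A intersect B| / |B|; 1 when B is empty."""
    a, b = set(a), set(b)
    if not b:
        return 1.0
    return len(a & b) / len(b)


def _exon_matches(pred: ExonNode, ref: ExonNode, strand: str) -> bool:
    """A predicted exon matches a reference exon when both bounded ends agree
    exactly; an unbounded end matches any reference extent, provided the
    exons overlap."""
    if not pred.interval.overlaps(ref.interval):
        return False
    if strand == "+":
        start_bounded, end_bounded = pred.acceptor_bounded, pred.donor_bounded
    else:
        start_bounded, end_bounded = pred.donor_bounded, pred.acceptor_bounded
    if start_bounded and pred.interval.start != ref.interval.start:
        return False
    if end_bounded and pred.interval.end != ref.interval.end:
        return False
    return True


def compare_graphs(predicted: SpliceGraph, reference: SpliceGraph) -> RecallReport:
    """Exon- and intron-level recall of a reference graph by a prediction."""
    if predicted.strand != reference.strand:
        ref_exons = list(reference.nodes.values())
        return RecallReport(
            0.0 if ref_exons else 1.0,
            0.0 if reference.edges else 1.0,
            0, len(ref_exons), 0, len(reference.edges),
            sum(1 for n in predicted.nodes.values() if not n.unresolved),
            len(predicted.edges),
        )
    strand = reference.strand
    pred_exons = [n for n in predicted.nodes.values() if not n.unresolved]
    ref_exons = [n for n in reference.nodes.values() if not n.unresolved]
    matched_refs = sum(
        1 for r in ref_exons if any(_exon_matches(p, r, strand) for p in pred_exons)
    )
    novel_exons = sum(
        1 for p in pred_exons if not any(_exon_matches(p, r, strand) for r in ref_exons)
    )
    pred_introns = {(i.start, i.end) for i in (predicted.intron(e) for e in predicted.edges)}
    ref_introns = {(i.start, i.end) for i in (reference.intron(e) for e in reference.edges)}
    matched_introns = len(pred_introns & ref_introns)
    exon_recall = matched_refs / len(ref_exons) if ref_exons else 1.0
    intron_recall = matched_introns / len(ref_introns) if ref_introns else 1.0
    return RecallReport(
        exon_recall,
        intron_recall,
        matched_refs,
        len(ref_exons),
        matched_introns,
        len(ref_introns),
        novel_exons,
        len(pred_introns - ref_introns),
    )


def pooled_recall(
    reports: Mapping[str, RecallReport]
) -> tuple[float, float]:
    """Genome-wide exon and intron recall pooled over genes."""
    me = sum(r.exons_matched for r in reports.values())
    te = sum(r.exons_total for r in reports.values())
    mi = sum(r.introns_matched for r in reports.values())
    ti = sum(r.introns_total for r in reports.values())
    return (me / te if te else 1.0, mi / ti if ti else 1.0)


def transcripts_to_graphs(
    predictions: Sequence[tuple[str, GenomicInterval, Sequence[GenomicInterval]]],
    models: Sequence[GeneModel],
) -> tuple[dict[str, SpliceGraph], list[str]]:
    """Convert external transcript predictions to per-gene splice graphs.

    Each transcript — (id, extent, exons) — is assigned to every same-strand
    gene it overlaps and the transcripts of each gene are merged with the EST
    rules (terminal exons unbounded).  Transcripts overlapping no gene are
    returned separately.
    """
    assigned: dict[str, list[tuple[str, Sequence[GenomicInterval]]]] = {}
    unassigned: list[str] = []
    for tid, extent, exons in predictions:
        hits = [
            m for m in models
            if m.interval.overlaps(extent) and m.interval.strand == extent.strand
        ]
        if not hits:
            unassigned.append(tid)
            continue
        for m in hits:
            assigned.setdefault(m.gene_id, []).append((tid, exons))
    graphs: dict[str, SpliceGraph] = {}
    by_id = {m.gene_id: m for m in models}
    for gene_id, txs in assigned.items():
        m = by_id[gene_id]
        first = est_graph_from_transcripts(gene_id, m.interval, txs[:1])
        for i in range(1, len(txs)):
            nxt = est_graph_from_transcripts(gene_id, m.interval, txs[i : i + 1])
            first = merge_est_graph(first, nxt)
        graphs[gene_id] = first
    return graphs, unassigned


def write_recall_report(
    reports: Mapping[str, RecallReport], path: str | Path
) -> None:
    """Per-gene recall table plus a pooled aggregate row."""
    with open(path, "w") as fh:
        fh.write(
            "gene\texon_recall\tintron_recall\tnovel_exons\tnovel_introns\n"
        )
        for gene_id in sorted(reports):
            r = reports[gene_id]
            fh.write(
                f"{gene_id}\t{r.exon_recall:.4f}\t{r.intron_recall:.4f}"
                f"\t{r.novel_exons}\t{r.novel_introns}\n"
            )
        er, ir = pooled_recall(reports)
        ne = sum(r.novel_exons for r in reports.values())
        ni = sum(r.novel_introns for r in reports.values())
        fh.write(f"ALL\t{er:.4f}\t{ir:.4f}\t{ne}\t{ni}\n")
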