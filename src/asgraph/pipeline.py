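"""End-to-end splice-graph prediction: annotation + RNA-Seq (+ ESTs) to graphs.

The stages mirror the method: build baseline graphs from gene models, merge
EST-derived graphs, filter ungapped alignments and tally per-gene coverage,
filter spliced alignments against known and predicted splice sites, then run
the event-inference rules per gene.  The baseline annotation is always
preserved in the output graphs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

from . import coords_io, depth
from .asinfer import ASEvent, run_inference
from .coords_io import GeneModel, ReadAlignment
from .graphmodel import SpliceGraph, est_graph_from_transcripts, graph_from_gene_model, merge_est_graph
from .junctions import (
    Junction,
    SiteCatalog,
    SplicedFilterParams,
    SpliceSite,
    accept_spliced_alignment,
    tally_junction_support,
)

log = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    graphs: dict[str, SpliceGraph]
    events: dict[str, list[ASEvent]]
    junctions: dict[str, list[Junction]]
    n_ungapped_accepted: int = 0
    n_spliced_accepted: int = 0
    n_spliced_rejected: int = 0

    def all_events(self) -> list[ASEvent]:
        out: list[ASEvent] = []
        for gene_id in sorted(self.events):
            out.extend(self.events[gene_id])
        return out


def merge_est_models(
    base_graphs: Mapping[str, SpliceGraph],
    models: Sequence[GeneModel],
    est_models: Sequence[GeneModel],
) -> dict[str, SpliceGraph]:
    """Merge EST/cDNA transcripts into baseline graphs of overlapping genes."""
    graphs = dict(base_graphs)
    for est in est_models:
        hits = [
            m for m in models
            if m.interval.overlaps(est.interval)
            and m.interval.strand == est.interval.strand
        ]
        if not hits:
            log.warning("EST %s overlaps no gene; skipped", est.gene_id)
            continue
        for m in hits:
            eg = est_graph_from_transcripts(m.gene_id, m.interval, est.transcripts)
            graphs[m.gene_id] = merge_est_graph(graphs[m.gene_id], eg)
    return graphs


def predict_graphs(
    models: Sequence[GeneModel],
    genome,
    alignments: Sequence[ReadAlignment],
    predicted_sites: Sequence[SpliceSite] = (),
    est_models: Sequence[GeneModel] | None = None,
    depth_threshold: int = 0,
    filter_params: SplicedFilterParams = SplicedFilterParams(),
) -> PipelineResult:
    """Predict a splice graph per gene from alignments and optional ESTs."""
    base = {m.gene_id: graph_from_gene_model(m) for m in models}
    if est_models:
        base = merge_est_models(base, models, est_models)
    ungapped = [a for a in alignments if not a.is_spliced]
    spliced = [a for a in alignments if a.is_spliced]
    accepted = coords_io.filter_ungapped_alignments(ungapped)
    catalog = SiteCatalog.build(models, genome, predicted_sites)
    decisions = [
        accept_spliced_alignment(a, models, catalog, genome, filter_params)
        for a in spliced
    ]
    n_ok = sum(1 for d in decisions if d.accepted)
    junctions = tally_junction_support(decisions)
    by_gene: dict[str, list[Junction]] = {}
    for j in junctions:
        by_gene.setdefault(j.gene_id, []).append(j)
    graphs: dict[str, SpliceGraph] = {}
    events: dict[str, list[ASEvent]] = {}
    for m in models:
        overlapping = [
            a for a in accepted
            if a.interval.chrom == m.interval.chrom
            and a.interval.overlaps(m.interval)
        ]
        dv = depth.depth_vector(m, overlapping)
        clusters = depth.assemble_clusters(
            dv, depth_threshold, m.interval.chrom, m.interval.strand
        )
        g, evs = run_inference(
            base[m.gene_id], clusters, by_gene.get(m.gene_id, []), depth_threshold
        )
        graphs[m.gene_id] = g
        events[m.gene_id] = evs
    log.info(
        "pipeline: %d genes, %d/%d ungapped accepted, %d/%d spliced accepted",
        len(models), len(accepted), len(ungapped), n_ok, len(spliced),
    )
    return PipelineResult(
        graphs=graphs,
        events=events,
        junctions=by_gene,
        n_ungapped_accepted=len(accepted),
        n_spliced_accepted=n_ok,
        n_spliced_rejected=len(spliced) - n_ok,
    )
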