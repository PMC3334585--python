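"""Shared fixtures: tiny in-memory graphs, genomes and simulated data sets."""

from __future__ import annotations

import pytest
from hypothesis import settings

from asgraph.coords_io import GeneModel, GenomicInterval

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")
from asgraph.graphmodel import ExonNode, SpliceGraph
from asgraph.junctions import Junction, SpliceSite


def interval(start, end, chrom="chr1", strand="+"):
    return GenomicInterval(chrom, start, end, strand)


def make_graph(gene_id, exons, edges, strand="+", chrom="chr1", span=None,
               unbounded=(), unresolved=(), provenance=None):
    """Build a splice graph from (start, end) pairs and index-pair edges.

    ``unbounded`` maps node index -> ("acceptor"|"donor"|"both").
    """
    span = span or (min(s for s, _ in exons), max(e for _, e in exons))
    g = SpliceGraph(gene_id, GenomicInterval(chrom, span[0], span[1], strand), strand)
    keys = []
    unbounded = dict(unbounded)
    for i, (s, e) in enumerate(exons):
        ub = unbounded.get(i)
        node = ExonNode(
            GenomicInterval(chrom, s, e, strand),
            acceptor_bounded=ub not in ("acceptor", "both"),
            donor_bounded=ub not in ("donor", "both"),
            provenance=(provenance or "gene_model"),
            unresolved=i in unresolved,
        )
        if node.unresolved:
            g.nodes[node.key] = node
        else:
            g.add_node(node)
        keys.append(node.key)
    for a, b in edges:
        g.add_edge(keys[a], keys[b])
    return g


def make_model(gene_id, transcripts, strand="+", chrom="chr1"):
    """GeneModel from lists of (start, end) exon pairs, one list per transcript."""
    all_exons = [e for tx in transcripts for e in tx]
    span = (min(s for s, _ in all_exons), max(e for _, e in all_exons))
    return GeneModel(
        gene_id,
        GenomicInterval(chrom, span[0], span[1], strand),
        tuple(
            (
                f"{gene_id}.{i + 1}",
                tuple(GenomicInterval(chrom, s, e, strand) for s, e in sorted(tx)),
            )
            for i, tx in enumerate(transcripts)
        ),
    )


def make_junction(intron, strand="+", chrom="chr1", gene_id="g1",
                  category="predicted", support=1,
                  donor_origin="known", acceptor_origin="known"):
    """Junction over the forward-axis intron (start, end)."""
    s, e = intron
    if strand == "+":
        donor = SpliceSite(chrom, strand, s, "donor", "GT", donor_origin)
        acceptor = SpliceSite(chrom, strand, e, "acceptor", "AG", acceptor_origin)
    else:
        donor = SpliceSite(chrom, strand, e, "donor", "GT", donor_origin)
        acceptor = SpliceSite(chrom, strand, s, "acceptor", "AG", acceptor_origin)
    return Junction(gene_id, donor, acceptor, category, support)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small simulated data set with one planted event of each type."""
    from asgraph import coords_io, simulate

    cfg = simulate.SimConfig(seed=11, n_genes=8)
    sim = simulate.simulate_genome(cfg)
    outdir = tmp_path_factory.mktemp("sim_small")
    paths = simulate.emit(sim, outdir)
    genome = coords_io.load_genome(paths["genome"])
    models = coords_io.read_gene_models(paths["models"])
    alignments = coords_io.read_alignments(paths["reads"], genome)
    return {
        "sim": sim,
        "paths": paths,
        "genome": genome,
        "models": models,
        "alignments": alignments,
    }
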