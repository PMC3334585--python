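"""Coordinate conversion, GFF3/SAM reading, alignment filters, graph round trips."""

from __future__ import annotations

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from asgraph import coords_io
from asgraph.coords_io import (
    FormatError,
    GenomicInterval,
    ParseError,
    ReadAlignment,
    filter_ungapped_alignments,
    read_gene_models,
    split_spliced_alignment,
)
from conftest import make_graph


# ---------------------------------------------------------------------------
# coordinates


def test_gff3_coordinate_convention():
    iv = GenomicInterval.from_gff3("chr1", 101, 200)
    assert (iv.start, iv.end) == (100, 200)
    assert iv.to_gff3() == (101, 200)


@given(
    start1=st.integers(min_value=1, max_value=10**8),
    length=st.integers(min_value=1, max_value=10**6),
    strand=st.sampled_from(["+", "-"]),
)
@settings(max_examples=200, deadline=None)
def test_gff3_round_trip_is_lossless(start1, length, strand):
    end1 = start1 + length - 1
    iv = GenomicInterval.from_gff3("chrX", start1, end1, strand)
    assert iv.to_gff3() == (start1, end1)
    assert iv.length == length


def test_invalid_interval_rejected():
    with pytest.raises(ValueError):
        GenomicInterval("chr1", 10, 10)
    with pytest.raises(ValueError):
        GenomicInterval("chr1", -1, 5)


# ---------------------------------------------------------------------------
# GFF3 gene models


GFF3_TWO_TX = """##gff-version 3
chr1\ttest\tgene\t101\t500\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t101\t500\t.\t+\t.\tID=g1.1;Parent=g1
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=g1.1.e1;Parent=g1.1
chr1\ttest\tCDS\t151\t200\t.\t+\t0\tID=g1.1.c1;Parent=g1.1
chr1\ttest\texon\t301\t500\t.\t+\t.\tID=g1.1.e2;Parent=g1.1
chr1\ttest\tmRNA\t101\t500\t.\t+\t.\tID=g1.2;Parent=g1
chr1\ttest\texon\t101\t200\t.\t+\t.\tID=g1.2.e1;Parent=g1.2
chr1\ttest\texon\t401\t500\t.\t+\t.\tID=g1.2.e2;Parent=g1.2
"""


def test_read_gene_models_unions_exonic_records(tmp_path):
    p = tmp_path / "m.gff3"
    p.write_text(GFF3_TWO_TX)
    models = read_gene_models(p)
    assert len(models) == 1
    m = models[0]
    assert m.gene_id == "g1"
    assert len(m.transcripts) == 2
    tx1 = dict(m.transcripts)["g1.1"]
    # CDS [151,200] nested in exon [101,200] collapses into one exon [100,200)
    assert [(e.start, e.end) for e in tx1] == [(100, 200), (300, 500)]


def test_read_gene_models_malformed_line(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("chr1\ttest\tgene\t1\t100\n")
    with pytest.raises(ParseError, match="line 1"):
        read_gene_models(p)


def test_read_gene_models_orphan_exon_skipped(tmp_path, caplog):
    p = tmp_path / "orphan.gff3"
    p.write_text(
        "##gff-version 3\n"
        "chr1\ttest\tgene\t101\t200\t.\t+\t.\tID=g1\n"
        "chr1\ttest\tmRNA\t101\t200\t.\t+\t.\tID=g1.1;Parent=g1\n"
        "chr1\ttest\texon\t101\t200\t.\t+\t.\tID=g1.1.e1;Parent=g1.1\n"
        "chr1\ttest\texon\t901\t999\t.\t+\t.\tID=orphan\n"
    )
    models = read_gene_models(p)
    assert len(models) == 1
    assert [(e.start, e.end) for e in dict(models[0].transcripts)["g1.1"]] == [(100, 200)]


# ---------------------------------------------------------------------------
# ungapped filter


def _aln(read_id="r", start=0, length=10, nm=0, unique=True, second=None):
    iv = GenomicInterval("chr1", start, start + length)
    return ReadAlignment(read_id, iv, (iv,), nm, (), unique, second)


@pytest.mark.parametrize(
    "aln, kept",
    [
        (_aln(nm=0, unique=True), True),
        (_aln(nm=1, unique=True), False),  # 100% identity required
        (_aln(nm=0, unique=False), False),
        (_aln(nm=0, second=0.93), False),  # competing hit above 90%
        (_aln(nm=0, second=0.85), True),
        (_aln(nm=None), False),  # no metadata: conservative reject
    ],
)
def test_filter_ungapped_rules(aln, kept):
    assert (filter_ungapped_alignments([aln]) == [aln]) is kept


def test_filter_ungapped_order_invariant():
    rng = random.Random(0)
    alns = [
        _aln(f"r{i}", nm=rng.choice([0, 0, 1]), unique=rng.random() < 0.8,
             second=rng.choice([None, 0.85, 0.95]))
        for i in range(50)
    ]
    shuffled = alns[:]
    rng.shuffle(shuffled)
    kept1 = {a.read_id for a in filter_ungapped_alignments(alns)}
    kept2 = {a.read_id for a in filter_ungapped_alignments(shuffled)}
    assert kept1 == kept2


# ---------------------------------------------------------------------------
# spliced decomposition


def _spliced(blocks):
    ivs = tuple(GenomicInterval("chr1", s, e) for s, e in blocks)
    return ReadAlignment("r", GenomicInterval("chr1", ivs[0].start, ivs[-1].end), ivs)


def test_split_cigar_20m100n12m():
    # 20M100N12M at 0-based position 1000
    blocks, introns = split_spliced_alignment(_spliced([(1000, 1020), (1120, 1132)]))
    assert [(b.start, b.end) for b in blocks] == [(1000, 1020), (1120, 1132)]
    assert [(i.start, i.end) for i in introns] == [(1020, 1120)]


def test_split_double_gap():
    # 10M50N10M50N12M
    blocks, introns = split_spliced_alignment(
        _spliced([(0, 10), (60, 70), (120, 132)])
    )
    assert len(introns) == 2
    assert [(i.start, i.end) for i in introns] == [(10, 60), (70, 120)]


def test_split_single_block_errors():
    with pytest.raises(ValueError):
        split_spliced_alignment(_aln())


def test_split_overlapping_blocks_error():
    with pytest.raises(FormatError):
        split_spliced_alignment(_spliced([(0, 20), (10, 30)]))


@given(
    st.lists(
        st.tuples(st.integers(1, 50), st.integers(1, 200)), min_size=2, max_size=5
    )
)
@settings(max_examples=200, deadline=None)
def test_split_conserves_reference_span(parts):
    # build blocks from alternating (block length, gap length) pairs
    pos = 100
    blocks = []
    for blen, gap in parts:
        blocks.append((pos, pos + blen))
        pos = pos + blen + gap
    a = _spliced(blocks)
    bs, ins = split_spliced_alignment(a)
    span = a.blocks[-1].end - a.blocks[0].start
    assert sum(b.length for b in bs) + sum(i.length for i in ins) == span


# ---------------------------------------------------------------------------
# SAM reading


def test_read_alignments_from_sam(tmp_path):
    genome = {"chr1": "ACGTACGTACGTACGTACGTACGTACGTACGT"}
    sam = tmp_path / "t.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:32\n"
        "r1\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGTACGT\t*\tNM:i:0\n"
        "r2\t0\tchr1\t1\t60\t4M8N4M\t*\t0\t0\tACGTACGT\t*\tNM:i:0\n"
        "r3\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGAACGT\t*\n"
    )
    alns = {a.read_id: a for a in coords_io.read_alignments(sam, genome)}
    assert not alns["r1"].is_spliced and alns["r1"].mismatches_total == 0
    assert alns["r2"].is_spliced
    assert [(b.start, b.end) for b in alns["r2"].blocks] == [(0, 4), (12, 16)]
    # r3 has no NM tag; mismatches recomputed against the genome
    assert alns["r3"].mismatches_total == 1
    assert alns["r3"].mismatch_positions == (3,)


def test_read_alignments_uniqueness_by_read_id(tmp_path):
    sam = tmp_path / "t.sam"
    sam.write_text(
        "@HD\tVN:1.6\n@SQ\tSN:chr1\tLN:100\n"
        "r1\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGTACGT\t*\tNM:i:0\n"
        "r1\t256\tchr1\t21\t0\t8M\t*\t0\t0\tACGTACGT\t*\tNM:i:0\n"
        "r2\t0\tchr1\t1\t60\t8M\t*\t0\t0\tACGTACGT\t*\tNM:i:0\n"
    )
    alns = {a.read_id: a for a in coords_io.read_alignments(sam)}
    assert not alns["r1"].is_unique
    assert alns["r2"].is_unique


# ---------------------------------------------------------------------------
# graph serialization


def test_graph_round_trip(tmp_path):
    g = make_graph("g1", [(0, 100), (200, 300), (400, 500)], [(0, 1), (1, 2)])
    path = tmp_path / "g.gff"
    coords_io.write_graph(g, path)
    assert coords_io.read_graph(path) == g


def test_graph_round_trip_preserves_flags(tmp_path):
    g = make_graph(
        "g1", [(0, 100), (200, 300), (350, 390)], [(0, 1)],
        unbounded={1: "donor"}, unresolved={2},
    )
    path = tmp_path / "g.gff"
    coords_io.write_graph(g, path)
    back = coords_io.read_graph(path)
    assert back == g
    assert back.nodes[(350, 390)].unresolved
    assert not back.nodes[(200, 300)].donor_bounded


def test_graph_round_trip_minus_strand(tmp_path):
    g = make_graph("g1", [(0, 100), (200, 300)], [(1, 0)], strand="-")
    path = tmp_path / "g.gff"
    coords_io.write_graph(g, path)
    assert coords_io.read_graph(path) == g


def test_graph_round_trip_empty(tmp_path):
    from asgraph.graphmodel import SpliceGraph

    g = SpliceGraph("g1", GenomicInterval("chr1", 0, 1000), "+")
    path = tmp_path / "g.gff"
    coords_io.write_graph(g, path)
    back = coords_io.read_graph(path)
    assert back == g and not back.nodes and not back.edges


def test_read_graph_unknown_record_type(tmp_path):
    path = tmp_path / "g.gff"
    path.write_text(
        "chr1\tasgraph\tgene\t1\t100\t.\t+\t.\tID=g1\n"
        "chr1\tasgraph\twidget\t1\t50\t.\t+\t.\tID=x\n"
    )
    with pytest.raises(ParseError, match="widget"):
        coords_io.read_graph(path)
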