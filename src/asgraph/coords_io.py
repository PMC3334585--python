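"""Coordinate conventions and I/O for gene models, alignments and splice-graph files.

All internal coordinates are 0-based, half-open and expressed on the forward
genomic axis.  GFF3 records (1-based, inclusive) and SAM records (1-based POS)
are converted at the boundary, so every module downstream of this one works
with a single convention.

The module also implements the two alignment filters applied before any graph
construction: the exact-match/unique-location filter for ungapped alignments
and the CIGAR ``N``-gap decomposition of spliced alignments into anchor blocks
and inferred introns.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import gffutils
import pysam
from pyfaidx import Fasta

log = logging.getLogger(__name__)

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

#: feature types whose coordinates contribute to exon extents in GFF3 input
EXONIC_TYPES = ("exon", "CDS", "five_prime_UTR", "three_prime_UTR", "UTR")

#: second-best alignment identity is carried in this optional SAM float tag
SECOND_BEST_TAG = "XB"


class FormatError(ValueError):
    """A record that does not satisfy the expectations of its format."""


class ParseError(FormatError):
    """A file that could not be parsed; message includes the line number."""


class ModelError(ValueError):
    """A gene model violating structural invariants (e.g. overlapping exons)."""


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC N preserved)."""
    return seq.translate(COMPLEMENT)[::-1]


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """Half-open interval [start, end) on the forward axis of ``chrom``."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def to_gff3(self) -> tuple[int, int]:
        """Convert to GFF3 1-based inclusive (start, end)."""
        return self.start + 1, self.end

    @classmethod
    def from_gff3(
        cls, chrom: str, start1: int, end1: int, strand: str = "+"
    ) -> "GenomicInterval":
        """Build from GFF3 1-based inclusive coordinates."""
        return cls(chrom, start1 - 1, end1, strand)


@dataclass(frozen=True)
class ReadAlignment:
    """A single read alignment; one block is ungapped, two or more is spliced."""

    read_id: str
    interval: GenomicInterval
    blocks: tuple[GenomicInterval, ...]
    mismatches_total: int | None = 0
    mismatch_positions: tuple[int, ...] = ()
    is_unique: bool = True
    second_best_identity: float | None = None
    sequence: str | None = None

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1

    @property
    def read_length(self) -> int:
        if self.sequence:
            return len(self.sequence)
        return sum(b.length for b in self.blocks)


@dataclass(frozen=True)
class GeneModel:
    """A gene with one or more transcripts, each an ordered tuple of exons.

    Exons are stored sorted on the forward axis; transcription order on the
    minus strand runs from the last exon to the first.
    """

    gene_id: str
    interval: GenomicInterval
    transcripts: tuple[tuple[str, tuple[GenomicInterval, ...]], ...]

    def introns(self) -> list[tuple[int, int]]:
        """Distinct annotated introns as (donor boundary, acceptor boundary)."""
        out = set()
        for _, exons in self.transcripts:
            for a, b in zip(exons, exons[1:]):
                if self.interval.strand == "+":
                    out.add((a.end, b.start))
                else:
                    out.add((b.start, a.end))
        return sorted(out)


# ---------------------------------------------------------------------------
# genome access


def load_genome(path: str | Path) -> Fasta:
    """Open a FASTA file for random access."""
    return Fasta(str(path), as_raw=True, sequence_always_upper=True)


def fetch(genome, chrom: str, start: int, end: int) -> str:
    """Forward-strand slice of the genome; works for pyfaidx and plain dicts."""
    seq = genome[chrom][start:end]
    return str(seq).upper()


def chrom_length(genome, chrom: str) -> int:
    return len(genome[chrom])


# ---------------------------------------------------------------------------
# GFF3 gene models


def _prescan_gff3(path: Path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            if stripped.startswith(">"):
                break  # embedded FASTA section
            if len(stripped.split("\t")) != 9:
                raise ParseError(
                    f"{path}: malformed GFF3 line {lineno}: "
                    "expected 9 tab-separated fields"
                )


def _union_intervals(parts: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals; overlapping or touching parts coalesce."""
    merged: list[list[int]] = []
    for s, e in sorted(parts):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def read_gene_models(gff3_path: str | Path) -> list[GeneModel]:
    """Read gene models from GFF3.

    Per transcript, UTR, CDS and exon records covering a contiguous stretch
    are unioned into maximal exon intervals.  Exonic records without a Parent
    are skipped with a warning.
    """
    path = Path(gff3_path)
    _prescan_gff3(path)
    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    n_orphans = 0
    for ftype in EXONIC_TYPES:
        for feat in db.features_of_type(ftype):
            if "Parent" not in feat.attributes:
                n_orphans += 1
                log.warning("orphan %s record at %s:%s skipped", ftype, feat.seqid, feat.start)
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene"):
        gi = GenomicInterval.from_gff3(gene.seqid, gene.start, gene.end, gene.strand)
        transcripts = []
        for tx in db.children(gene, level=1):
            parts = [
                (f.start - 1, f.end)
                for f in db.children(tx, level=1)
                if f.featuretype in EXONIC_TYPES
            ]
            if not parts:
                continue
            exons = tuple(
                GenomicInterval(gene.seqid, s, e, gene.strand)
                for s, e in _union_intervals(parts)
            )
            transcripts.append((tx.id, exons))
        models.append(GeneModel(gene.id, gi, tuple(transcripts)))
    log.info("read %d gene models from %s (%d orphan records skipped)",
             len(models), path, n_orphans)
    return models


# ---------------------------------------------------------------------------
# SAM alignments


def _cigar_walk(rec: pysam.AlignedSegment) -> tuple[list[tuple[int, int]], list[tuple[int, int, int]]]:
    """Decompose a CIGAR into reference blocks and (qpos, rpos, length) match runs.

    Blocks close only at N operations; deletions extend the current block on
    the reference.  Returns ([(block_start, block_end), ...], match_runs).
    """
    blocks: list[tuple[int, int]] = []
    runs: list[tuple[int, int, int]] = []
    rpos = rec.reference_start
    qpos = 0
    bstart = rpos
    open_block = False
    for op, ln in rec.cigartuples or ():
        if op in (0, 7, 8):  # M, =, X
            runs.append((qpos, rpos, ln))
            rpos += ln
            qpos += ln
            open_block = True
        elif op == 2:  # D
            rpos += ln
            open_block = True
        elif op == 3:  # N closes the block: the gap is an inferred intron
            if open_block:
                blocks.append((bstart, rpos))
            rpos += ln
            bstart = rpos
            open_block = False
        elif op in (1, 4):  # I, S consume query only
            qpos += ln
        elif op == 5:  # H
            pass
        else:
            raise FormatError(f"unsupported CIGAR op {op} in read {rec.query_name}")
    if open_block:
        blocks.append((bstart, rpos))
    return blocks, runs


def _mismatch_positions(
    runs: Sequence[tuple[int, int, int]], seq: str, genome, chrom: str
) -> tuple[int, ...]:
    positions = []
    for qpos, rpos, ln in runs:
        ref = fetch(genome, chrom, rpos, rpos + ln)
        for k in range(ln):
            if seq[qpos + k].upper() != ref[k]:
                positions.append(rpos + k)
    return tuple(positions)


def read_alignments(sam_path: str | Path, genome=None) -> list[ReadAlignment]:
    """Stream a SAM file into :class:`ReadAlignment` records.

    Mismatch counts come from the NM tag when present, otherwise they are
    recomputed against ``genome`` if one is supplied; alignments with neither
    carry ``mismatches_total=None`` and are rejected downstream.  Uniqueness
    is taken from the NH tag when present, else from the absence of any other
    alignment record for the same read id.
    """
    with pysam.AlignmentFile(str(sam_path), "r", check_sq=False) as sam:
        raw = [r for r in sam if not r.is_unmapped]
    name_counts = Counter(r.query_name for r in raw)
    out: list[ReadAlignment] = []
    for rec in raw:
        if rec.is_secondary or rec.is_supplementary:
            continue
        chrom = rec.reference_name
        block_pairs, runs = _cigar_walk(rec)
        blocks = tuple(GenomicInterval(chrom, s, e) for s, e in block_pairs)
        seq = rec.query_sequence
        nm = rec.get_tag("NM") if rec.has_tag("NM") else None
        mpos: tuple[int, ...] = ()
        if genome is not None and seq:
            mpos = _mismatch_positions(runs, seq, genome, chrom)
            if nm is None:
                nm = len(mpos)
        if rec.has_tag("NH"):
            unique = rec.get_tag("NH") == 1
        else:
            unique = name_counts[rec.query_name] == 1
        second = (
            float(rec.get_tag(SECOND_BEST_TAG))
            if rec.has_tag(SECOND_BEST_TAG)
            else None
        )
        out.append(
            ReadAlignment(
                read_id=rec.query_name,
                interval=GenomicInterval(chrom, blocks[0].start, blocks[-1].end),
                blocks=blocks,
                mismatches_total=nm,
                mismatch_positions=mpos,
                is_unique=unique,
                second_best_identity=second,
                sequence=seq,
            )
        )
    log.info("read %d primary alignments from %s", len(out), sam_path)
    return out


def filter_ungapped_alignments(
    alignments: Iterable[ReadAlignment],
    max_second_best: float = 0.90,
) -> list[ReadAlignment]:
    """Keep alignments that match the reference exactly at a unique location.

    An alignment is kept iff it has zero mismatches, is unique, and either has
    no reported competing hit or its second-best hit falls below
    ``max_second_best`` identity.  Alignments without mismatch metadata are
    rejected conservatively.
    """
    accepted: list[ReadAlignment] = []
    reasons: Counter[str] = Counter()
    for a in alignments:
        if a.mismatches_total is None:
            reasons["no_mismatch_metadata"] += 1
        elif a.mismatches_total > 0:
            reasons["identity"] += 1
        elif not a.is_unique:
            reasons["not_unique"] += 1
        elif a.second_best_identity is not None and a.second_best_identity >= max_second_best:
            reasons["second_best"] += 1
        else:
            accepted.append(a)
    log.info(
        "ungapped filter: %d accepted, rejections: %s",
        len(accepted),
        dict(reasons) or "none",
    )
    return accepted


def split_spliced_alignment(
    a: ReadAlignment,
) -> tuple[tuple[GenomicInterval, ...], tuple[GenomicInterval, ...]]:
    """Decompose a spliced alignment into anchor blocks and inferred introns."""
    if len(a.blocks) < 2:
        raise ValueError(f"alignment {a.read_id} is not spliced")
    blocks = tuple(sorted(a.blocks, key=lambda b: b.start))
    for left, right in zip(blocks, blocks[1:]):
        if right.start < left.end:
            raise FormatError(f"overlapping blocks in alignment {a.read_id}")
        if right.start == left.end:
            raise FormatError(f"zero-length intron in alignment {a.read_id}")
    introns = tuple(
        GenomicInterval(a.interval.chrom, left.end, right.start)
        for left, right in zip(blocks, blocks[1:])
    )
    return blocks, introns


# ---------------------------------------------------------------------------
# splice graph GFF dialect
#
# One ``exon`` record per node, carrying boundedness, provenance and the
# unresolved flag as attributes; one ``intron`` record per edge, keyed by the
# donor- and acceptor-side node ids.  A single ``gene`` record carries the
# gene extent.

_GRAPH_SOURCE = "asgraph"


def _fmt_attrs(attrs: dict[str, str]) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items())


def _parse_attrs(text: str) -> dict[str, str]:
    out = {}
    for item in text.strip().split(";"):
        if item and "=" in item:
            k, v = item.split("=", 1)
            out[k] = v
    return out


def write_graph(graph, path: str | Path) -> None:
    """Serialize a splice graph to the package's GFF dialect."""
    keys = sorted(graph.nodes)
    node_ids = {k: f"{graph.gene_id}:n{i}" for i, k in enumerate(keys)}
    gi = graph.interval
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        s1, e1 = gi.to_gff3()
        fh.write(
            "\t".join(
                [gi.chrom, _GRAPH_SOURCE, "gene", str(s1), str(e1), ".",
                 gi.strand, ".", _fmt_attrs({"ID": graph.gene_id})]
            )
            + "\n"
        )
        for k in keys:
            node = graph.nodes[k]
            s1, e1 = node.interval.to_gff3()
            attrs = {
                "ID": node_ids[k],
                "Parent": graph.gene_id,
                "AcceptorBounded": str(int(node.acceptor_bounded)),
                "DonorBounded": str(int(node.donor_bounded)),
                "Provenance": node.provenance,
                "Unresolved": str(int(node.unresolved)),
            }
            fh.write(
                "\t".join(
                    [gi.chrom, _GRAPH_SOURCE, "exon", str(s1), str(e1), ".",
                     gi.strand, ".", _fmt_attrs(attrs)]
                )
                + "\n"
            )
        for u, v in sorted(graph.edges):
            intron = graph.intron((u, v))
            s1, e1 = intron.to_gff3()
            attrs = {
                "ID": f"{graph.gene_id}:e{node_ids[u]}-{node_ids[v]}",
                "Parent": graph.gene_id,
                "Donor": node_ids[u],
                "Acceptor": node_ids[v],
            }
            fh.write(
                "\t".join(
                    [gi.chrom, _GRAPH_SOURCE, "intron", str(s1), str(e1), ".",
                     gi.strand, ".", _fmt_attrs(attrs)]
                )
                + "\n"
            )


def read_graph(path: str | Path):
    """Read a splice graph written by :func:`write_graph`."""
    from .graphmodel import ExonNode, SpliceGraph

    graph = None
    nodes_by_id: dict[str, tuple[int, int]] = {}
    pending_edges: list[tuple[str, str]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            stripped = line.rstrip("\n")
            if not stripped or stripped.startswith("#"):
                continue
            fields = stripped.split("\t")
            if len(fields) != 9:
                raise ParseError(f"{path}: malformed line {lineno}")
            chrom, _, ftype, s1, e1, _, strand, _, attr_text = fields
            attrs = _parse_attrs(attr_text)
            interval = GenomicInterval.from_gff3(chrom, int(s1), int(e1), strand)
            if ftype == "gene":
                graph = SpliceGraph(attrs["ID"], interval, strand)
            elif ftype == "exon":
                if graph is None:
                    raise ParseError(f"{path}: exon before gene at line {lineno}")
                node = ExonNode(
                    interval=interval,
                    acceptor_bounded=attrs.get("AcceptorBounded", "1") == "1",
                    donor_bounded=attrs.get("DonorBounded", "1") == "1",
                    provenance=attrs.get("Provenance", "gene_model"),
                    unresolved=attrs.get("Unresolved", "0") == "1",
                )
                graph.add_node(node)
                nodes_by_id[attrs["ID"]] = node.key
            elif ftype == "intron":
                pending_edges.append((attrs["Donor"], attrs["Acceptor"]))
            else:
                raise ParseError(
                    f"{path}: unknown record type {ftype!r} at line {lineno}"
                )
    if graph is None:
        raise ParseError(f"{path}: no gene record found")
    for did, aid in pending_edges:
        graph.add_edge(nodes_by_id[did], nodes_by_id[aid])
    return graph
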