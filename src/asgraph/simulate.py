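"""Synthetic genomes, gene models and read alignments with known truth.

The generator emulates the inputs the pipeline consumes in a real study:
multi-exon genes on both strands with canonical GT-AG introns whose site
neighborhoods follow configurable consensus motifs, a constitutive annotated
isoform per gene, and for a configurable subset of genes one additional
unannotated isoform carrying a planted alternative-splicing event (intron
retention, exon skipping, or an alternative 5'/3' site).  Reads are sampled
uniformly along isoforms and emitted as already-aligned SAM records —
ungapped within exons, spliced with correct blocks across junctions — with a
configurable per-base error rate; alignment ambiguity is simulated through
explicit second-best-identity metadata rather than by running an aligner.

Everything is deterministic given the seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pysam

from .coords_io import GeneModel, GenomicInterval, revcomp
from .graphmodel import SpliceGraph, graph_from_gene_model
from .junctions import SpliceSite

log = logging.getLogger(__name__)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated data set."""

    seed: int = 42
    n_genes: int = 20
    chrom: str = "chrSim"
    exons_per_gene: tuple[int, int] = (3, 5)
    exon_length: tuple[int, int] = (90, 180)
    intron_length: tuple[int, int] = (70, 140)
    intergenic: tuple[int, int] = (300, 500)
    read_length: int = 32
    coverage: float = 30.0
    error_rate: float = 0.0
    #: fraction of genes given one unannotated isoform with a planted event
    event_fraction: float = 0.5
    event_types: tuple[str, ...] = ("IR", "ES", "Alt5", "Alt3")
    #: genomic shift of planted alternative donor/acceptor sites
    alt_offset: tuple[int, int] = (15, 40)
    #: consensus around splice sites (coding strand); dimers are forced exact
    donor_motif_exon: str = "CAG"
    donor_motif_intron: str = "GTAAGT"
    acceptor_motif_intron: str = "TCTTTCAG"
    acceptor_motif_exon: str = "G"
    motif_fidelity: float = 0.9
    #: include planted isoforms in the emitted annotation (multi-transcript genes)
    annotate_events: bool = False
    #: fraction of ungapped reads tagged with a competing 95%-identity hit
    multimap_fraction: float = 0.0
    #: drop spliced reads with a junction overlap below this many nucleotides
    min_emitted_anchor: int = 1


@dataclass(frozen=True)
class TruthEvent:
    """A planted event, identified by the coordinates that evidence it."""

    gene_id: str
    type: str
    intron: tuple[int, int]  # forward-axis novel/retained intron
    exon: tuple[int, int] | None = None  # skipped exon for ES


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    models: list[GeneModel]
    truth_transcripts: dict[str, list[tuple[str, tuple[GenomicInterval, ...]]]]
    truth_events: list[TruthEvent]
    novel_sites: list[SpliceSite]

    def truth_graphs(self) -> dict[str, SpliceGraph]:
        """Graphs of the annotated baseline models."""
        return {m.gene_id: graph_from_gene_model(m) for m in self.models}


# ---------------------------------------------------------------------------
# motif planting


def _sample_motif(consensus: str, forced: Sequence[int], fidelity: float, rng) -> str:
    out = []
    for i, c in enumerate(consensus):
        if i in forced or rng.random() < fidelity:
            out.append(c)
        else:
            out.append(chr(BASES[rng.integers(4)]))
    return "".join(out)


def _plant_site(
    genome: np.ndarray, boundary: int, role: str, strand: str, cfg: SimConfig, rng
) -> None:
    """Write a splice-site motif around an intron-edge boundary."""
    if role == "donor":
        window = cfg.donor_motif_exon + cfg.donor_motif_intron
        forced = (len(cfg.donor_motif_exon), len(cfg.donor_motif_exon) + 1)
        exon_len = len(cfg.donor_motif_exon)
        intron_len = len(cfg.donor_motif_intron)
    else:
        window = cfg.acceptor_motif_intron + cfg.acceptor_motif_exon
        forced = (len(cfg.acceptor_motif_intron) - 2, len(cfg.acceptor_motif_intron) - 1)
        exon_len = len(cfg.acceptor_motif_exon)
        intron_len = len(cfg.acceptor_motif_intron)
    sampled = _sample_motif(window, forced, cfg.motif_fidelity, rng)
    if role == "donor":
        if strand == "+":
            lo = boundary - exon_len
            seq = sampled
        else:
            lo = boundary - intron_len
            seq = revcomp(sampled)
    else:
        if strand == "+":
            lo = boundary - intron_len
            seq = sampled
        else:
            lo = boundary - exon_len
            seq = revcomp(sampled)
    genome[lo : lo + len(seq)] = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# genome + models


def _gene_structure(cfg: SimConfig, rng, cursor: int) -> tuple[list[tuple[int, int]], int]:
    n_exons = int(rng.integers(cfg.exons_per_gene[0], cfg.exons_per_gene[1] + 1))
    exons = []
    pos = cursor
    for i in range(n_exons):
        if i > 0:
            pos += int(rng.integers(cfg.intron_length[0], cfg.intron_length[1] + 1))
        length = int(rng.integers(cfg.exon_length[0], cfg.exon_length[1] + 1))
        exons.append((pos, pos + length))
        pos = exons[-1][1]
    return exons, pos


def _variant_exons(
    exons: list[tuple[int, int]],
    etype: str,
    strand: str,
    delta: int,
    j: int,
) -> tuple[list[tuple[int, int]], tuple[int, int], tuple[int, int] | None]:
    """Exon list of the planted isoform, its novel/retained intron, and the
    skipped exon for ES.  ``j`` indexes an internal exon on the forward axis."""
    if etype == "IR":
        merged = (exons[j][0], exons[j + 1][1])
        variant = exons[:j] + [merged] + exons[j + 2 :]
        intron = (exons[j][1], exons[j + 1][0])
        return variant, intron, None
    if etype == "ES":
        variant = exons[:j] + exons[j + 1 :]
        intron = (exons[j - 1][1], exons[j + 1][0])
        return variant, intron, exons[j]
    if etype == "Alt3":
        if strand == "+":
            new = (exons[j][0] - delta, exons[j][1])
            intron = (exons[j - 1][1], new[0])
        else:
            new = (exons[j][0], exons[j][1] + delta)
            intron = (new[1], exons[j + 1][0])
    elif etype == "Alt5":
        if strand == "+":
            new = (exons[j][0], exons[j][1] + delta)
            intron = (new[1], exons[j + 1][0])
        else:
            new = (exons[j][0] - delta, exons[j][1])
            intron = (exons[j - 1][1], new[0])
    else:
        raise ValueError(f"unknown event type {etype!r}")
    variant = exons[:j] + [new] + exons[j + 1 :]
    return variant, intron, None


def simulate_genome(cfg: SimConfig) -> SimResult:
    """Generate a genome, baseline annotation and planted-event truth."""
    rng = np.random.default_rng(cfg.seed)
    if cfg.alt_offset[1] + 25 > cfg.intron_length[0]:
        raise ValueError("alt_offset too large for the shortest intron")
    if cfg.exons_per_gene[0] < 3:
        raise ValueError("event planting needs at least 3 exons per gene")
    structures = []
    cursor = 0
    for _ in range(cfg.n_genes):
        cursor += int(rng.integers(cfg.intergenic[0], cfg.intergenic[1] + 1))
        exons, cursor = _gene_structure(cfg, rng, cursor)
        strand = "+" if rng.random() < 0.5 else "-"
        structures.append((exons, strand))
    genome_len = cursor + int(rng.integers(cfg.intergenic[0], cfg.intergenic[1] + 1))
    genome = BASES[rng.integers(0, 4, size=genome_len)].copy()

    n_events = int(round(cfg.event_fraction * cfg.n_genes))
    event_genes = {
        i: cfg.event_types[i % len(cfg.event_types)] for i in range(n_events)
    }

    models: list[GeneModel] = []
    truth_transcripts: dict[str, list[tuple[str, tuple[GenomicInterval, ...]]]] = {}
    truth_events: list[TruthEvent] = []
    novel_sites: list[SpliceSite] = []
    for gi, (exons, strand) in enumerate(structures):
        gene_id = f"g{gi + 1:03d}"
        # constitutive splice sites
        for (a_end, b_start) in ((exons[k][1], exons[k + 1][0]) for k in range(len(exons) - 1)):
            if strand == "+":
                _plant_site(genome, a_end, "donor", strand, cfg, rng)
                _plant_site(genome, b_start, "acceptor", strand, cfg, rng)
            else:
                _plant_site(genome, b_start, "donor", strand, cfg, rng)
                _plant_site(genome, a_end, "acceptor", strand, cfg, rng)
        etype = event_genes.get(gi)
        variant = None
        if etype is not None:
            j = 1 + int(rng.integers(0, len(exons) - 2))  # internal exon
            delta = int(rng.integers(cfg.alt_offset[0], cfg.alt_offset[1] + 1))
            variant, intron, skipped = _variant_exons(exons, etype, strand, delta, j)
            truth_events.append(TruthEvent(gene_id, etype, intron, skipped))
            if etype in ("Alt3", "Alt5"):
                role = "acceptor" if etype == "Alt3" else "donor"
                boundary = (
                    intron[1] if (role == "acceptor") == (strand == "+") else intron[0]
                )
                _plant_site(genome, boundary, role, strand, cfg, rng)
                novel_sites.append(
                    SpliceSite(cfg.chrom, strand, boundary, role,
                               "AG" if role == "acceptor" else "GT", "predicted")
                )
        gene_iv = GenomicInterval(cfg.chrom, exons[0][0], exons[-1][1], strand)
        if variant is not None:
            gene_iv = GenomicInterval(
                cfg.chrom,
                min(gene_iv.start, variant[0][0]),
                max(gene_iv.end, variant[-1][1]),
                strand,
            )
        to_iv = lambda pairs: tuple(
            GenomicInterval(cfg.chrom, s, e, strand) for s, e in pairs
        )
        annotated = [(f"{gene_id}.1", to_iv(exons))]
        truth = list(annotated)
        if variant is not None:
            truth.append((f"{gene_id}.2", to_iv(variant)))
            if cfg.annotate_events:
                annotated.append((f"{gene_id}.2", to_iv(variant)))
        models.append(GeneModel(gene_id, gene_iv, tuple(annotated)))
        truth_transcripts[gene_id] = truth

    genome_str = genome.tobytes().decode("ascii")
    return SimResult(
        cfg, {cfg.chrom: genome_str}, models, truth_transcripts, truth_events, novel_sites
    )


# ---------------------------------------------------------------------------
# reads


def _read_blocks(
    exons: Sequence[GenomicInterval], t_start: int, n: int
) -> list[tuple[int, int]]:
    """Map a transcript-coordinate read [t_start, t_start+n) to genomic blocks."""
    blocks = []
    offset = 0
    remaining = n
    for e in exons:
        elen = e.length
        if t_start >= offset + elen:
            offset += elen
            continue
        lo = e.start + max(0, t_start - offset)
        take = min(remaining, e.end - lo)
        blocks.append((lo, lo + take))
        remaining -= take
        offset += elen
        if remaining == 0:
            break
    return blocks


def simulate_reads(sim: SimResult, cfg: SimConfig | None = None) -> list[dict]:
    """Sample reads from the truth isoforms; returns SAM-ready record dicts."""
    cfg = cfg or sim.config
    rng = np.random.default_rng([cfg.seed, 7])
    n = cfg.read_length
    chrom = cfg.chrom
    seq = sim.genome[chrom]
    reads: list[dict] = []
    for gene_id in sorted(sim.truth_transcripts):
        for tx_id, exons in sim.truth_transcripts[gene_id]:
            tx_len = sum(e.length for e in exons)
            if tx_len < n:
                raise ValueError(
                    f"read length {n} exceeds transcript {tx_id} ({tx_len} nt)"
                )
            n_reads = int(np.ceil(cfg.coverage * tx_len / n))
            starts = rng.integers(0, tx_len - n + 1, size=n_reads)
            for k, t_start in enumerate(starts):
                blocks = _read_blocks(exons, int(t_start), n)
                if len(blocks) > 1 and (
                    blocks[0][1] - blocks[0][0] < cfg.min_emitted_anchor
                    or blocks[-1][1] - blocks[-1][0] < cfg.min_emitted_anchor
                ):
                    continue
                bases = list("".join(seq[s:e] for s, e in blocks))
                n_err = 0
                if cfg.error_rate > 0:
                    err = rng.random(n) < cfg.error_rate
                    for i in np.flatnonzero(err):
                        old = bases[i]
                        choices = [b for b in "ACGT" if b != old]
                        bases[i] = choices[int(rng.integers(3))]
                        n_err += 1
                tags = [("NM", n_err)]
                if (
                    len(blocks) == 1
                    and cfg.multimap_fraction > 0
                    and rng.random() < cfg.multimap_fraction
                ):
                    tags.append(("XB", 0.95))
                reads.append(
                    {
                        "name": f"{tx_id}:{k}",
                        "chrom": chrom,
                        "pos": blocks[0][0],
                        "blocks": blocks,
                        "seq": "".join(bases),
                        "tags": tags,
                    }
                )
    return reads


def write_sam(reads: Iterable[dict], genome: dict[str, str], path: str | Path) -> int:
    """Write simulated reads as a text SAM file."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in sorted(genome.items())],
    }
    ref_ids = {sq["SN"]: i for i, sq in enumerate(header["SQ"])}
    count = 0
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment()
            a.query_name = r["name"]
            a.flag = 0
            a.reference_id = ref_ids[r["chrom"]]
            a.reference_start = r["pos"]
            a.mapping_quality = 60
            cigar = []
            blocks = r["blocks"]
            for i, (s, e) in enumerate(blocks):
                if i > 0:
                    cigar.append((3, s - blocks[i - 1][1]))  # N
                cigar.append((0, e - s))  # M
            a.cigartuples = cigar
            a.query_sequence = r["seq"]
            a.set_tags(r["tags"])
            out.write(a)
            count += 1
    return count


# ---------------------------------------------------------------------------
# file emission


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name in sorted(genome):
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gi = m.interval
            s1, e1 = gi.to_gff3()
            fh.write(
                f"{gi.chrom}\tsim\tgene\t{s1}\t{e1}\t.\t{gi.strand}\t.\tID={m.gene_id}\n"
            )
            for tx_id, exons in m.transcripts:
                ts1 = exons[0].start + 1
                te1 = exons[-1].end
                fh.write(
                    f"{gi.chrom}\tsim\tmRNA\t{ts1}\t{te1}\t.\t{gi.strand}\t.\t"
                    f"ID={tx_id};Parent={m.gene_id}\n"
                )
                for i, e in enumerate(exons, 1):
                    es1, ee1 = e.to_gff3()
                    fh.write(
                        f"{gi.chrom}\tsim\texon\t{es1}\t{ee1}\t.\t{gi.strand}\t.\t"
                        f"ID={tx_id}.exon{i};Parent={tx_id}\n"
                    )


def write_truth_events(events: Iterable[TruthEvent], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene\ttype\tintron_start\tintron_end\texon\n")
        for ev in events:
            exon = f"{ev.exon[0]}-{ev.exon[1]}" if ev.exon else "."
            fh.write(
                f"{ev.gene_id}\t{ev.type}\t{ev.intron[0]}\t{ev.intron[1]}\t{exon}\n"
            )


def emit(sim: SimResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + GFF3 + SAM + truth tables to a directory."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "genome": outdir / "genome.fa",
        "models": outdir / "models.gff3",
        "reads": outdir / "reads.sam",
        "truth_events": outdir / "truth_events.tsv",
    }
    write_fasta(sim.genome, paths["genome"])
    write_gff3(sim.models, paths["models"])
    write_sam(simulate_reads(sim), sim.genome, paths["reads"])
    write_truth_events(sim.truth_events, paths["truth_events"])
    return paths
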