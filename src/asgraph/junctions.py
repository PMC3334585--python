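"""Splice sites, junctions, the junction sequence database, and spliced-read filtering.

A splice site is identified by the genomic coordinate of the intron edge it
defines (half-open convention): for an intron [s, e) on the plus strand the
donor boundary is s and the acceptor boundary is e; on the minus strand the
roles swap.  Dimers are always read in coding-strand orientation and the
scope is restricted to canonical GT/GC donors and AG acceptors.

Junctions fall into three categories: *known* junctions occur as annotated
introns, *recombined* junctions pair two known sites that never co-occur in a
transcript, and *predicted* junctions involve at least one classifier-derived
site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .coords_io import (
    GeneModel,
    GenomicInterval,
    ReadAlignment,
    chrom_length,
    fetch,
    revcomp,
    split_spliced_alignment,
)

log = logging.getLogger(__name__)

CANONICAL_DIMERS = (("GT", "AG"), ("GC", "AG"))
DONOR_DIMERS = ("GT", "GC")
ACCEPTOR_DIMERS = ("AG",)


@dataclass(frozen=True)
class SpliceSite:
    """A strand-aware donor or acceptor site at an intron edge."""

    chrom: str
    strand: str
    boundary: int
    role: str  # "donor" | "acceptor"
    dimer: str
    origin: str = "known"  # "known" | "predicted"
    score: float | None = None

    @property
    def key(self) -> tuple[str, str, int, str]:
        return (self.chrom, self.strand, self.boundary, self.role)


@dataclass(frozen=True)
class Junction:
    """A donor/acceptor pair within one gene, with read support."""

    gene_id: str
    donor: SpliceSite
    acceptor: SpliceSite
    category: str  # "known" | "recombined" | "predicted"
    support: int = 0

    @property
    def strand(self) -> str:
        return self.donor.strand

    @property
    def intron(self) -> GenomicInterval:
        if self.strand == "+":
            return GenomicInterval(
                self.donor.chrom, self.donor.boundary, self.acceptor.boundary, "+"
            )
        return GenomicInterval(
            self.donor.chrom, self.acceptor.boundary, self.donor.boundary, "-"
        )

    @property
    def key(self) -> tuple:
        return (self.donor.key, self.acceptor.key)


@dataclass(frozen=True)
class JunctionDBParams:
    """Geometry of the junction sequence database.

    Reads of length ``read_length`` (n) required to overlap a junction by at
    least ``min_overlap`` (p) nucleotides on either side map uniquely onto
    junction sequences of length 2(n - p).
    """

    read_length: int = 32
    min_overlap: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.min_overlap < self.read_length):
            raise ValueError("require 0 < min_overlap < read_length")

    @property
    def flank(self) -> int:
        return self.read_length - self.min_overlap


@dataclass(frozen=True)
class SplicedFilterParams:
    """Acceptance rules for spliced alignments."""

    min_anchor: int = 10
    min_identity: float = 0.90
    dimers: tuple[tuple[str, str], ...] = CANONICAL_DIMERS


# ---------------------------------------------------------------------------
# site extraction from annotation


def intron_dimers(genome, chrom: str, start: int, end: int, strand: str) -> tuple[str, str]:
    """(donor, acceptor) dimers of the forward-axis intron [start, end)."""
    if strand == "+":
        return fetch(genome, chrom, start, start + 2), fetch(genome, chrom, end - 2, end)
    return (
        revcomp(fetch(genome, chrom, end - 2, end)),
        revcomp(fetch(genome, chrom, start, start + 2)),
    )


def sites_from_gene_models(
    models: Iterable[GeneModel], genome, canonical_only: bool = True
) -> dict[str, list[SpliceSite]]:
    """Annotated splice sites per gene, read from transcript adjacency."""
    out: dict[str, list[SpliceSite]] = {}
    n_skipped = 0
    for m in models:
        strand = m.interval.strand
        chrom = m.interval.chrom
        sites: dict[tuple, SpliceSite] = {}
        for dboundary, aboundary in m.introns():
            s, e = (
                (dboundary, aboundary) if strand == "+" else (aboundary, dboundary)
            )
            ddimer, adimer = intron_dimers(genome, chrom, s, e, strand)
            if canonical_only and (ddimer, adimer) not in CANONICAL_DIMERS:
                n_skipped += 1
                continue
            d = SpliceSite(chrom, strand, dboundary, "donor", ddimer, "known")
            a = SpliceSite(chrom, strand, aboundary, "acceptor", adimer, "known")
            sites[d.key] = d
            sites[a.key] = a
        out[m.gene_id] = list(sites.values())
    if n_skipped:
        log.warning("skipped %d non-canonical annotated introns", n_skipped)
    return out


@dataclass
class SiteCatalog:
    """Known and predicted sites plus annotated intron pairs, for filtering."""

    known: set[tuple] = field(default_factory=set)
    predicted: set[tuple] = field(default_factory=set)
    known_pairs: set[tuple] = field(default_factory=set)

    @classmethod
    def build(
        cls,
        models: Iterable[GeneModel],
        genome,
        predicted_sites: Iterable[SpliceSite] = (),
    ) -> "SiteCatalog":
        cat = cls()
        models = list(models)
        by_gene = sites_from_gene_models(models, genome)
        for sites in by_gene.values():
            cat.known.update(s.key for s in sites)
        for m in models:
            strand = m.interval.strand
            for d, a in m.introns():
                cat.known_pairs.add((m.interval.chrom, strand, d, a))
        cat.predicted.update(s.key for s in predicted_sites)
        return cat

    def supports(self, key: tuple) -> bool:
        return key in self.known or key in self.predicted

    def categorize(self, chrom: str, strand: str, dboundary: int, aboundary: int) -> str:
        if (chrom, strand, dboundary, aboundary) in self.known_pairs:
            return "known"
        dknown = (chrom, strand, dboundary, "donor") in self.known
        aknown = (chrom, strand, aboundary, "acceptor") in self.known
        return "recombined" if dknown and aknown else "predicted"


# ---------------------------------------------------------------------------
# junction enumeration and sequences


def enumerate_junctions(
    gene: GeneModel,
    known_sites: Sequence[SpliceSite],
    predicted_sites: Sequence[SpliceSite] = (),
) -> list[Junction]:
    """Pair every donor site with all acceptor sites downstream of it.

    All sites belong to the same gene; downstream is defined in transcription
    order.  Categories: known if the pair occurs as an annotated intron,
    recombined if both sites are known but never paired, predicted if either
    site is novel.
    """
    strand = gene.interval.strand
    sites: dict[tuple, SpliceSite] = {}
    for s in list(known_sites) + list(predicted_sites):
        if s.key not in sites:  # known sites win over predicted duplicates
            sites[s.key] = s
    donors = [s for s in sites.values() if s.role == "donor"]
    acceptors = [s for s in sites.values() if s.role == "acceptor"]
    known_pairs = {
        (d, a) for d, a in gene.introns()
    }
    out = []
    for d in donors:
        for a in acceptors:
            downstream = (
                a.boundary > d.boundary if strand == "+" else a.boundary < d.boundary
            )
            if not downstream:
                continue
            if (d.boundary, a.boundary) in known_pairs:
                cat = "known"
            elif d.origin == "known" and a.origin == "known":
                cat = "recombined"
            else:
                cat = "predicted"
            out.append(Junction(gene.gene_id, d, a, cat))
    return out


def junction_sequence(
    j: Junction, genome, params: JunctionDBParams
) -> str | None:
    """The 2(n-p) database sequence for a junction: (n-p) exonic nucleotides
    upstream of the donor concatenated with (n-p) downstream of the acceptor,
    in coding-strand orientation.  Returns None (with a warning) when a flank
    would run off the chromosome."""
    f = params.flank
    chrom = j.donor.chrom
    clen = chrom_length(genome, chrom)
    if j.strand == "+":
        ds, de = j.donor.boundary - f, j.donor.boundary
        as_, ae = j.acceptor.boundary, j.acceptor.boundary + f
        if ds < 0 or ae > clen:
            log.warning("junction %s flank exceeds chromosome bounds; skipped", j.key)
            return None
        return fetch(genome, chrom, ds, de) + fetch(genome, chrom, as_, ae)
    ds, de = j.donor.boundary, j.donor.boundary + f
    as_, ae = j.acceptor.boundary - f, j.acceptor.boundary
    if as_ < 0 or de > clen:
        log.warning("junction %s flank exceeds chromosome bounds; skipped", j.key)
        return None
    return revcomp(fetch(genome, chrom, ds, de)) + revcomp(fetch(genome, chrom, as_, ae))


def build_junction_database(
    genes: Iterable[GeneModel],
    sites_by_gene: Mapping[str, Sequence[SpliceSite]],
    genome,
    params: JunctionDBParams,
    predicted_by_gene: Mapping[str, Sequence[SpliceSite]] | None = None,
) -> list[tuple[Junction, str]]:
    """Enumerate junctions for every gene and attach database sequences."""
    out = []
    for gene in genes:
        known = sites_by_gene.get(gene.gene_id, ())
        predicted = (predicted_by_gene or {}).get(gene.gene_id, ())
        for j in enumerate_junctions(gene, known, predicted):
            seq = junction_sequence(j, genome, params)
            if seq is not None:
                out.append((j, seq))
    return out


def write_junction_fasta(entries: Iterable[tuple[Junction, str]], path: str | Path) -> int:
    """Emit the junction database as FASTA; headers encode gene, sites, category."""
    n = 0
    with open(path, "w") as fh:
        for j, seq in entries:
            header = (
                f"{j.gene_id}|{j.donor.chrom}|{j.strand}"
                f"|donor:{j.donor.boundary}|acceptor:{j.acceptor.boundary}"
                f"|{j.category}"
            )
            fh.write(f">{header}\n{seq}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# spliced-alignment acceptance


@dataclass(frozen=True)
class Decision:
    """Outcome of spliced-alignment filtering, with a reason code on reject."""

    accepted: bool
    reason: str | None = None
    junctions: tuple[Junction, ...] = ()


def _hosting_gene(
    genes: Sequence[GeneModel], intron: GenomicInterval
) -> GeneModel | None:
    hosts = [
        g
        for g in genes
        if g.interval.chrom == intron.chrom
        and g.interval.start <= intron.start
        and intron.end <= g.interval.end
    ]
    return hosts[0] if len(hosts) == 1 else None


def accept_spliced_alignment(
    a: ReadAlignment,
    genes: Sequence[GeneModel],
    catalog: SiteCatalog,
    genome,
    params: SplicedFilterParams = SplicedFilterParams(),
) -> Decision:
    """Accept or reject one spliced alignment.

    Per inferred intron the alignment must (i) span canonical GT-AG or GC-AG
    dimers on the coding strand, (ii) use sites that are annotated or
    classifier-positive, (iii) stay within a single gene, (iv) anchor with at
    least ``min_anchor`` exact-match nucleotides on both sides, and (v) reach
    ``min_identity`` overall identity.  The first violated rule gives the
    reason code.
    """
    blocks, introns = split_spliced_alignment(a)
    chrom = a.interval.chrom
    host = None
    for intron in introns:
        h = _hosting_gene(genes, intron)
        if h is None or (host is not None and h.gene_id != host.gene_id):
            return Decision(False, "multi_gene")
        host = h
    strand = host.interval.strand
    site_pairs = []
    for intron in introns:
        ddimer, adimer = intron_dimers(genome, chrom, intron.start, intron.end, strand)
        if (ddimer, adimer) not in params.dimers:
            return Decision(False, "non_canonical")
        if strand == "+":
            dboundary, aboundary = intron.start, intron.end
        else:
            dboundary, aboundary = intron.end, intron.start
        site_pairs.append((dboundary, ddimer, aboundary, adimer))
    for dboundary, _, aboundary, _ in site_pairs:
        if not catalog.supports((chrom, strand, dboundary, "donor")):
            return Decision(False, "false_positive_site")
        if not catalog.supports((chrom, strand, aboundary, "acceptor")):
            return Decision(False, "false_positive_site")
    p = params.min_anchor
    for i in range(len(introns)):
        left, right = blocks[i], blocks[i + 1]
        if left.length < p or right.length < p:
            return Decision(False, "short_anchor")
    mpos = a.mismatch_positions
    if not mpos and a.mismatches_total:
        # positions unknown but mismatches exist: cannot prove clean anchors
        return Decision(False, "anchor_mismatch")
    for i in range(len(introns)):
        left, right = blocks[i], blocks[i + 1]
        anchor_ranges = ((left.end - p, left.end), (right.start, right.start + p))
        for lo, hi in anchor_ranges:
            if any(lo <= m < hi for m in mpos):
                return Decision(False, "anchor_mismatch")
    n = a.read_length
    mismatches = a.mismatches_total or 0
    if n and (n - mismatches) / n < params.min_identity:
        return Decision(False, "low_identity")
    out = []
    for dboundary, ddimer, aboundary, adimer in site_pairs:
        dorigin = "known" if (chrom, strand, dboundary, "donor") in catalog.known else "predicted"
        aorigin = "known" if (chrom, strand, aboundary, "acceptor") in catalog.known else "predicted"
        out.append(
            Junction(
                host.gene_id,
                SpliceSite(chrom, strand, dboundary, "donor", ddimer, dorigin),
                SpliceSite(chrom, strand, aboundary, "acceptor", adimer, aorigin),
                catalog.categorize(chrom, strand, dboundary, aboundary),
                support=1,
            )
        )
    return Decision(True, None, tuple(out))


def tally_junction_support(decisions: Iterable[Decision]) -> list[Junction]:
    """Aggregate accepted decisions into one junction per site pair with its
    total crossing-read count.  Double-gapped reads increment every junction
    they cross."""
    counts: dict[tuple, Junction] = {}
    for d in decisions:
        if not d.accepted:
            continue
        for j in d.junctions:
            prev = counts.get(j.key)
            if prev is None:
                counts[j.key] = j
            else:
                counts[j.key] = replace(prev, support=prev.support + j.support)
    return sorted(counts.values(), key=lambda j: (j.gene_id, j.intron.start, j.intron.end))
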