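# Methods

## The model

`asgraph` predicts per-gene *splice graphs*: directed graphs in which nodes
are exons and edges are the introns connecting them in transcription order,
so that every path corresponds to a possible transcript. The method treats a
curated annotation as a trusted baseline and only *adds* structure supported
by evidence — short-read coverage, filtered spliced alignments, and EST/cDNA
transcripts — so the baseline annotation is recapitulated exactly in every
prediction (exon and intron recall of the input models is 1 by
construction). Whenever evidence is compatible with more than one isoform,
the signal is annotated as an *unresolved* node rather than forced into a
typed event; unresolved nodes never receive edges and never contribute to
event counts.

Exon ends are named in transcript orientation: the acceptor end is the 5'
end of the exon, the donor end the 3' end; on the minus strand the acceptor
end is the higher genomic coordinate. An end is *bounded* when an explicit
splice site defines it. Internally all coordinates are 0-based half-open on
the forward genomic axis; GFF3 and SAM are converted at the I/O boundary.

## Alignment filtering

Ungapped alignments are accepted only with zero mismatches at a unique
location, and only if no competing hit reaches 90% identity. Mismatch counts
come from the NM tag, or are recomputed against the genome; alignments with
neither are rejected conservatively. Competing-hit identity is carried in a
custom SAM float tag `XB` (there is no standard tag for it); uniqueness uses
NH when present, else the per-read-id record count.

Spliced alignments must, per inferred intron: span canonical GT-AG/GC-AG
dimers on the coding strand; use splice sites that are annotated or
classifier-positive; lie within a single gene; anchor with at least `p` = 10
exact-match nucleotides on both sides of every junction; and reach 90%
overall identity. The first violated rule yields a machine-readable reason
code (`multi_gene`, `non_canonical`, `false_positive_site`, `short_anchor`,
`anchor_mismatch`, `low_identity`).

Both spliced-alignment workflows are supported: filtering an external
spliced aligner's SAM (the default), and building a junction sequence
database — every donor paired with every downstream acceptor in the same
gene, each sequence being (n−p) exonic nucleotides either side of the
junction, length 2(n−p) — against which an ungapped mapper can be run. The
database route is practical only for compact genomes.

## Event inference

Rules run in a fixed order; evidence consumed by one rule is not reused.

1. **Intron retention.** A coverage cluster spanning an intron's full length
   evidences retention. The retained exon runs from the shared acceptor of
   the exons overlapping the cluster's 5' side to the shared donor of those
   on its 3' side; if either side is ambiguous, or the cluster covers two or
   more distinct introns, the cluster becomes an unresolved node. A second
   scenario fires when an accepted novel junction falls strictly inside a
   known exon: the exon is split into two bounded sub-exons and the known
   exon is recorded as the retained form.
2. **Alternative 3'/5' sites.** Both evidence forms are required: a cluster
   overlapping an exon and extending into its flanking intron, *and* an
   accepted junction with a site inside that intron. The junction site
   nearest the cluster end gives the new boundary; the opposite end resolves
   only if all overlapping exons on that side share one site. Variation at
   the donor is an Alt5 event, at the acceptor an Alt3 event, in transcript
   orientation.
3. **Exon skipping.** A novel junction whose donor and acceptor match
   established exons and whose intron contains an exon marks that exon as
   skipped. Conversely an intronic cluster flanked by two novel junctions
   whose outer sites associate with graph exons becomes a novel
   (constitutively skipped) exon bounded by the junctions' inner sites.

Finally, edge assembly completes connectivity: each new exon copies the
incoming edges of exons sharing its acceptor site and the outgoing edges of
exons sharing its donor site, iterated to a fixed point.

Event classification on arbitrary graphs uses site-level predicates (IR: a
node strictly containing another pair's intron; ES: an intron containing a
connected node; Alt5/Alt3: two introns sharing one boundary), de-duplicated
by the set of splice sites involved, per gene.

## Splice-site classifiers

One soft-margin SVM per (dimer, role), with a weighted-degree string kernel

    k(x, y) = sum_{d=1..D} beta_d sum_i [x[i:i+d] == y[i:i+d]],
    beta_d = 2 (D - d + 1) / (D (D + 1)),

evaluated with a single pass over positions by tracking matching-run lengths
(a run of length r gains sum_{d<=min(r,D)} beta_d per position). Positives
are annotated sites; negatives are every other in-gene occurrence of the
dimer. Grid search over degree, window geometry and the SVM C is scored by
stratified five-fold cross-validated ROC AUC (seeded splits); the best point
is refit on all data. Class imbalance is handled by per-class error
weighting. Positional shifts (weight 1/(2s) at shift s) and within-k-mer
mismatches (a d-mer with ≤ M mismatches scores beta_d — a simplification of
the per-(d,m) weightings in the kernel literature) are grid options and
default off. The decision threshold defaults to the SVM margin (0) and can
be recalibrated. Classifiers persist as versioned JSON (parameters, support
windows, dual coefficients, bias).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| depth threshold | 0 | clusters require depth strictly above it (≥ 1 read) |
| min anchor `p` | 10 nt | exact-match overlap required on each side of a junction |
| min identity | 0.90 | overall spliced-read identity (denominator: read length) |
| dimers | GT-AG, GC-AG | canonical intron boundaries considered |
| kernel degree D | 4 | longest substring scored by the WD kernel |
| window geometry | 12 exonic + 15 intronic nt | classifier context around the dimer |
| CV folds | 5 | stratified, seeded |

## The simulator

The generator emulates the study conditions the pipeline is designed for:
multi-exon genes on both strands (3–5 exons of 90–180 nt, introns of 70–140
nt, intergenic gaps of 300–500 nt), canonical splice sites whose
neighborhoods follow consensus motifs (donor `CAG|GTAAGT`, acceptor
`TCTTTCAG|G`, per-position fidelity 0.9, dimers forced), one constitutive
annotated isoform per gene, and for a configurable fraction of genes one
unannotated isoform carrying a planted IR, ES, Alt5 or Alt3 event
(alternative sites shifted 15–40 nt into the intron, with a canonical motif
planted at the novel boundary). Reads (default 32 nt at 30× per isoform,
error-free unless configured) are sampled uniformly along isoforms and
emitted as already-aligned SAM, so tests are hermetic: no aligner runs, and
ambiguity is expressed through explicit second-best-identity metadata.

What the simulator does **not** model: base-quality profiles, coverage
biases (GC, positional), paired-end inserts, overlapping genes, non-canonical
introns, misalignments, or genuine multi-mapping. Passing tests therefore
demonstrate the correctness of the graph/inference machinery and the
filters' behavior on well-formed evidence, not robustness to real-library
artifacts. In the event round-trip checks the planted novel sites are
supplied to the pipeline as the site-prediction input, so event inference is
exercised independently of classifier quality, which is measured separately
(motif-vs-uniform recovery, held-out ROC > 0.9, label-permutation null at
0.5).

## Numerical and design choices

- "Above a minimum threshold" is read strictly (> t), so the default 0 keeps
  zero-coverage positions out of exons.
- Cluster-end snapping searches only within the gene, never crosses a
  baseline exon, and breaks distance ties toward the shorter exon.
- When two unbounded exons merge, the merged extent is the union of their
  intervals; a bounded exon pins the extent. Duplicate nodes collapse with
  provenance priority gene_model > est > short_read > inferred.
- A cluster covering two or more distinct introns is a single unresolved
  annotation (one retention event cannot be distinguished from several).
- A junction used to split an exon (retention scenario 2) is not reused for
  skipping inference; one inference pass never chains off its own products.
- Kernel self-similarity is constant across equal-length windows at S=0,
  M=0, so kernel normalization is omitted (absorbed by C).
- Graphs serialize to a GFF dialect: one `exon` record per node carrying
  boundedness/provenance/unresolved attributes, one `intron` record per
  edge; write∘read is the identity.

## Problem sizes

The bundled checks use desk-scale instances chosen to exercise every code
path: 50 simulated genes for the recall property, 32 genes (8 per type) for
event round trips, 1000+1000 windows for classifier recovery, and 1000
randomized instances per brute-force oracle comparison (junction
enumeration, depth clustering, WD kernel, ROC AUC, event classification).

## Known limitations

- Terminal-exon extensions (past a gene's first or last exon) are ignored
  rather than modeled as alternative transcription start/end.
- Exon matching in recall uses exact boundaries at bounded ends and
  one-sided matching at unbounded ends; other matching conventions would
  change novel-exon counts (recorded for sensitivity analysis).
- The junction-database workflow emits the database but does not map reads;
  mapping is external, and mapped junction reads re-enter as spliced SAM.
- Only GT-AG/GC-AG introns are in scope; AT-AC and other minor classes are
  rejected as non-canonical.
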