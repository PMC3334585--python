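# asgraph

Splice-graph prediction from curated gene models, RNA-Seq alignments and
EST/cDNA evidence — for transcriptomics researchers who want to detect
alternative splicing (AS) without trusting every spliced alignment a mapper
produces.

## What it does

Short reads rarely support a novel isoform unambiguously. `asgraph`
therefore predicts, per gene, a **splice graph** — exons as nodes, introns
as directed edges, paths as possible transcripts — that *enhances* an
annotated baseline rather than assembling transcripts de novo: every exon
and intron of the input annotation is preserved (recall 1.0 by
construction), new structure is added only when the evidence resolves a
single isoform, and ambiguous signals are kept as explicitly *unresolved*
annotations.

The core machinery:

- **Strict alignment filters.** Ungapped reads count only at 100% identity
  in a unique location with no competing hit at ≥ 90% identity. A spliced
  read is accepted only if each inferred intron spans canonical GT-AG/GC-AG
  dimers, uses annotated or classifier-positive splice sites, stays within
  one gene, anchors with ≥ p (default 10) exact-match nucleotides on both
  sides of the junction, and reaches 90% overall identity.
- **Splice-site classifiers.** One SVM per dimer/role with a weighted-degree
  string kernel, k(x,y) = Σ_{d≤D} β_d Σ_i [x[i:i+d] = y[i:i+d]] with
  β_d = 2(D−d+1)/(D(D+1)), trained on annotated sites vs. all other in-gene
  dimer occurrences, selected by stratified five-fold cross-validated ROC.
- **Junction database.** Every donor paired with every downstream acceptor
  in the same gene; each sequence is (n−p) exonic nucleotides on either side
  of the junction — length 2(n−p), e.g. 44 nt for 32-nt reads with p = 10 —
  so an ordinary ungapped mapper can detect junction-crossing reads.
- **Event inference.** Ordered rules integrate coverage clusters and
  accepted junctions into the graph as intron retention (IR), exon skipping
  (ES) and alternative 5'/3' events, or as unresolved nodes when boundaries
  are ambiguous; recall-based comparison (R(A|B) = |A∩B|/|B|, R(A|∅) = 1)
  scores predictions against references at the exon and intron level.
- **A truth-known simulator** generating genomes, annotations, planted AS
  events and pre-aligned reads, so the whole pipeline is testable hermetically.

## Worked example

Simulate a small data set (8 genes, half carrying one unannotated AS
isoform), predict graphs, and inspect one:

```sh
asgraph simulate --seed 7 --genes 8 --outdir sim
asgraph predict-graphs --genome sim/genome.fa --models sim/models.gff3 \
    --sam sim/reads.sam --sites sim/novel_sites.tsv --outdir out
asgraph events --graph out/g001.graph.gff
```

prints

```
events: IR=1, ES=1, Alt5=1, Alt3=1, unresolved=0; graphs -> out
gene g001 chrSim:489-1386(-)
  5 exons, 4 introns
  exon 1291-1386 (gene_model)
  exon 1041-1386 (short_read)
  exon 1041-1206 (gene_model)
  ...
  events: IR=1, ES=0, Alt5=0, Alt3=0
```

All four planted events were recovered, one per gene; in `g001` (minus
strand) read coverage across the intron 1206–1291 produced the retained-
intron exon 1041–1386 alongside the annotated exons. `out/events.tsv` lists
each event with its supporting evidence, e.g.

```
gene   type  resolved  nodes      introns    evidence
g001   IR    1         1041-1386  1206-1291  scenario=coverage;min_depth=2
g003   Alt5  1         3510-3658  3424-3510  junction_support=20
```

where `junction_support` is the number of accepted reads crossing the novel
junction. `asgraph compare --predicted ... --reference ...` reports exon and
intron recall plus novel-element counts.

Other subcommands: `train-sites` / `predict-sites` (splice-site
classifiers), `make-junctions` (the 2(n−p) junction FASTA), `filter-sam`
(spliced-read acceptance with reason codes), `merge-ests`.

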