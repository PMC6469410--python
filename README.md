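# beesplice

Characterization of alternative splicing (AS) from bulk RNA-seq derivatives
— splice-junction calls, per-base coverage, a genome and its gene models —
in the style of insect (honey bee) transcriptome studies. The package
detects and quantifies four AS classes, augments gene models with novel
exons and intergenic transcripts, scores splice-site strength with a
maximum-entropy motif model, and relates splicing to DNA methylation via
CpG observed/expected ratios and BS-seq calls. A first-class synthetic-data
generator plants every event type with known ground truth, so the whole
pipeline is testable without any external dataset.

## Who it is for

Researchers analysing AS in compact genomes where isoform-level
quantification is impractical and analysis proceeds directly from junction
evidence: the inputs are a genome FASTA, a GFF3 annotation, a junction TSV
(one intron per line with a confidence score and supporting-read count, the
information content of a TrueSight/TopHat junction file), a bedGraph
coverage track, and optionally BS-seq methylation calls and an ortholog
table.

## The statistics at the core

With the upstream exon `a~b`, event region `p~q` (alternatives `p'`, `q'`)
and downstream exon `c~d`, junction support `N(x~y)` and mean coverage
`Cov(x,y)`:

* **Intron retention (IR)** — intron `p~q` is retained when every intronic
  base exceeds 5x depth and the inclusion ratio
  `2·Cov(p,q) / (Cov(a,p) + Cov(q,d))` is at least three times the
  genome-wide baseline (default 0.017). The ratio is deliberately not
  clamped at 1.
* **Cassette exon (CE)** — an internal exon skipped by a junction `b~c`
  joining its neighbours; inclusion ratio
  `((N(b~p)+N(q~c))/2) / ((N(b~p)+N(q~c))/2 + N(b~c))`.
* **Alternative exon boundary (AEB)** — a half-annotated junction shifting
  a donor (5') or acceptor (3') site by fewer than 200 nt; splicing ratio
  `min(N,N')/max(N,N')` (minor over major isoform) and an inclusion ratio
  for the disputed boundary region.
* **Alternative terminal exons (AFE/ALE)** — distinct first/last exons
  splicing into the same constitutive acceptor/donor site; quantified by
  the same minor/major splicing ratio.
* **Splice-site strength** — `log2 P_model(w)/P_bg(w)` for the 9-nt donor
  (3 exonic + 6 intronic) or 23-nt acceptor (20 intronic + 3 exonic)
  window `w`, where `P_model` is a maximum-entropy distribution fitted to
  annotated sites (order 1: positional marginals = a PWM; order 2: adjacent
  pairwise marginals, fitted exactly by iterative proportional scaling on
  the chain).
* **CpG(o/e)** — `P_CpG/(P_C·P_G)`, a depletion-based proxy for germline
  methylation; plus BS-seq classification of regions as
  methylated/unmethylated.

Group comparisons (site strength or CpG metrics across inclusion- or
splicing-ratio bins) use two-sided Mann-Whitney-Wilcoxon tests between the
extreme occupied bins, reported as raw p-values.

## Worked example

Generate a dataset with 50 planted events and run the full pipeline:

```sh
beesplice simulate --seed 5 --out demo/data
# -> wrote 50 planted events to demo/data
beesplice report \
  --genome demo/data/genome.fa --gff demo/data/annotation.gff3 \
  --junctions demo/data/junctions.tsv --coverage demo/data/coverage.bedgraph \
  --methylation demo/data/methylation.tsv --out demo/report
```

which prints the per-kind count table (event count, involved exons —
both flanks for an IR — and genes undergoing AS):

```
        kind  number  exons_involved  genes
          IR      10              20     10
          CE      10              10     10
   ALT_DONOR      10              10     10
ALT_ACCEPTOR      10              10     10
         AFE       5              10      5
         ALE       5              10      5
```

Every planted event is recovered and nothing else: the junction-evidence
detectors admit no false positives on this data, and the noise floor
(0.017x intronic coverage) stays far below the IR criteria. `demo/report/`
contains the augmented GFF3 (novel features tagged with source
`beesplice`), the per-event table `events.tsv` with all coordinates and
ratios, the displacement spectrum, and a JSON manifest of all parameters.

The same operations are available as a library:

```python
from beesplice.synthetic_data import SimulationConfig, simulate
from beesplice.analysis_report import PipelineConfig, run_pipeline

dataset = simulate(SimulationConfig(seed=5, n_genes=60, n_ce=10, n_ir=10))
bundle = run_pipeline(PipelineConfig(seed=0), dataset=dataset)
print(bundle.table1)
```

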