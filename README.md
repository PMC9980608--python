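# mvi — multiomic virome integration

A pipeline for integrating metagenome (MG), metavirome (MV), and
metatranscriptome (MT) sequencing views of a gut viral community:

- **`mvi.io_model`** — core data model (contigs, samples, count/breadth
  matrices, genes, host scores), TSV/FASTA readers and writers, bundle
  validation.
- **`mvi.synthetic`** — a ground-truthed synthetic community generator:
  free phages, prophages embedded in host contigs with flanking regions,
  participant x site log-normal abundance structure, dataset-specific
  detection, planted integrase/repressor gene content, and
  inflammation-graded host contamination.
- **`mvi.clustering`** — greedy containment clustering (95% identity over
  90% of the smaller contig by default) with exact-substring, k-mer-anchor
  and alignment paths; cross-dataset source classification; IC vs NI
  (integration-capable vs non-integrated) calls from pruned-flank flags and
  containment in non-viral contigs; prophage masking.
- **`mvi.abundance`** — breadth-of-coverage filtering (>= 75%, MG/MV only),
  length-normalized relative abundance (NRA), viral fractions,
  contamination QC.
- **`mvi.transcription`** — transcriptional-activity calls (MT NRA >=
  0.0001%) on complete/high-quality VCs, transcribed-gene calls (> 1 MT
  counts), transcription ratios, cross-dataset NRA correlations.
- **`mvi.lysogeny`** — integrase term detection, gene-family IC/NI
  statistics, integration likelihood ratios (sensitivity / (1 −
  specificity)), transcribed-fraction contrasts.
- **`mvi.ecology`** — seeded rarefaction, Chao1, Shannon, population
  variance, Bray-Curtis contrasts with PCoA, per-participant 3-site VC
  set overlaps, matched vs null phage-host abundance correlations.
- **`mvi.depth`** — detection-based sequencing-depth saturation curves
  with nested subsampling and knee estimation.

## CLI

`mvi simulate` writes a complete plain-text fixture bundle (FASTA, contig
tables, genes, tri-omic count/breadth tables, sample sheet, truth labels):

```sh
mvi simulate --seed 5 --outdir fx/
mvi cluster   --contigs fx/contigs.fasta --meta fx/contigs.tsv --out clusters/
mvi abundance --counts fx/counts_MV.tsv --contigs fx/catalog.tsv \
              --samples fx/samples.tsv --dataset MV --out nra_MV.tsv
mvi transcribe --nra-mt nra_MT.tsv --nra-mg nra_MG.tsv --genes fx/genes.tsv \
               --gene-counts-mt fx/gene_counts_MT.tsv --contigs fx/catalog.tsv \
               --samples fx/samples.tsv --out ta_calls.tsv
mvi lysogeny  --genes fx/genes.tsv --vc-class clusters/vc_class.tsv \
              --contigs fx/catalog.tsv --out lysogeny_stats.tsv
mvi ecology   --counts fx/counts_MV.tsv --samples fx/samples.tsv \
              --dataset MV --out ecology/
mvi depth     --truth fx/truth.tsv --out depthcurve.tsv
mvi validate  --config run.yaml
```

Notes: `fx/contigs.tsv` lists the raw per-dataset assemblies fed to
clustering, while `fx/catalog.tsv` is the dereplicated catalog matching the
count-table rows. In synthetic bundles the cluster representative ids carry
`.MV`/`.MG` assembly suffixes; `mvi.synthetic.canonical_vc_id` maps them
back to catalog ids.

## Conventions

- Gene coordinates are 1-based inclusive on disk (GFF3 convention),
  0-based half-open internally.
- Tables are tab-separated UTF-8; `#` comment lines allowed.
- Missing samples (e.g. no stool metatranscriptome) are absent, never
  zero-filled.
- All stochastic operations take explicit seeds and are bit-reproducible.
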