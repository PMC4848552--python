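# mircontext

Analysis pipeline for studying how **genomic context and host-gene age shape
the expression and evolution of miRNAs**.

Most human miRNAs lie inside protein-coding genes ("intragenic", mostly in
introns and on the host's sense strand), and the genes that host them are
disproportionately evolutionarily ancient. `mircontext` implements the
statistical machinery needed to characterise and test this pattern:

- **Context classification** — each miRNA precursor is classified against
  gene models as intergenic or intragenic; intragenic precursors get a
  sense/antisense orientation and an intron / CDS-exon / UTR subregion
  against the host's longest transcript. Nearby miRNAs (gap ≤ 10 kb) are
  merged into clusters represented by one random member, and intergenic
  miRNAs get closest-neighbour gene distances.
- **Branch-age dating** — per-species, per-method ortholog hits (length
  ratio within [0.70, 1.30] of the query) are reduced to presence calls
  (≥ 2 methods with overlapping loci, or adoption of an annotated ortholog
  covering ≥ 50% of the hit). The age of a miRNA is the most ancient branch
  of a 12-branch vertebrate species tree with a presence call (Dollo
  parsimony); ages are binned into classes 1 (vertebrates), 2–4 (amniotes),
  5–6 (placental mammals) and 7–12 (primates). Per-branch origination rates
  are counts per Myr with a two-sided exact binomial test of the
  inter/intragenic split.
- **Expression quantification** — reads fully contained in a mature miRNA
  extended 3 nt at its 3′ end are counted with weight 1/L for L mapped loci,
  normalised to counts per million, collapsed to tissues by the median, and
  reduced to one profile per precursor (most highly expressed arm, identical
  mature sequences deduplicated to the oldest precursor, ≥ 1 c.p.m. in ≥ 1
  tissue).
- **Statistics** — expression breadth via the tissue-specificity index

  τ = Σᵢ (1 − x̂ᵢ) / (N − 1),  x̂ᵢ = log₂(cpmᵢ+1) / maxⱼ log₂(cpmⱼ+1),

  a **constrained resampling null** for host ages (each miRNA draws a gene
  *as old or older* than itself from the gene pool; the observed old-host
  fraction is compared against 10,000 such draws, with a χ² variant),
  a **tissue rank-order permutation test** of miRNA–host co-expression
  (3,000 label shuffles), cross-species expression divergence (Euclidean
  distance of log₂ profiles over a 5-tissue panel), Fisher-z comparison of
  correlations, exact Fisher/binomial tests, Ka/Ks distribution comparison
  and target-count filtering (7mer-m8/8mer sites with context score
  < −0.25).
- **Conservation** — mean per-base conservation score of each precursor and
  its seed (mature positions 2–8), contrasted against 100 equal-length
  random backgrounds from host introns (intragenic) or a ±10 kb gene-free
  window (intergenic).
- **Synthetic data** — a generator that emits the full input bundle (GFF3,
  BED6, TSV, bedGraph) with planted gene/miRNA ages, host-age bias,
  breadth and co-expression structure and conservation means, so every
  stage is testable against known ground truth without downloads.

## Worked example

```python
from mircontext import GeneratorConfig, PipelineConfig, run_pipeline, simulate_bundle

paths = simulate_bundle(GeneratorConfig(n_genes=200, n_mirnas=150, seed=7), "demo")
cfg = PipelineConfig(
    genes_gff3=paths["genes_gff3"], precursor_bed=paths["precursor_bed"],
    mature_bed=paths["mature_bed"], gene_ages_tsv=paths["gene_ages_tsv"],
    hits_tsv=paths["hits_tsv"], annotated_orthologs_tsv=paths["annotated_orthologs_tsv"],
    reads_tsv=paths["reads_tsv"], samples_tsv=paths["samples_tsv"],
    gene_expression_tsv=paths["gene_expression_tsv"], track_bedgraph=paths["track_bedgraph"],
    species_tree_yaml=paths["species_tree_yaml"], outdir="demo_out", seed=7,
)
report = run_pipeline(cfg)
```

which prints (via the report fields):

```
93 of 150 miRNAs intragenic (62.0%), 71 host genes
old-host fraction 0.823 vs null mean 0.668, empirical P = 1.40e-03 (10000 draws)
tau median, old hosts 0.120 vs young hosts 0.326 (MWU P = 6.6e-09)
co-expression rank match 0.444 vs null 0.200, empirical P = 3.33e-04
```

Reading: the generator planted an ~83% bias of intragenic miRNAs into
oldest-branch hosts; the constrained resampling test recovers the excess
(0.823 observed vs 0.668 expected under the age-matched null, empirical P
well below 0.05). miRNAs inside old hosts are more broadly expressed (lower
τ) than those inside young hosts, and miRNA–host tissue rank orders agree
far beyond the shuffle null — the planted co-expression.

The same stages are available from the shell:

```sh
mircontext simulate --seed 7 --outdir demo
mircontext run-all --config pipeline.yaml --seed 7 --outdir demo_out
```

(`classify`, `age`, `quantify`, `stats` and `conserve` run individual
stages; `--config` takes a flat YAML with the `PipelineConfig` keys.)

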