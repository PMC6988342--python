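# mgnet

Integrated analysis of paired host gene expression (RNA-seq counts) and
mucosal 16S microbiome data, exercised end-to-end on synthetic data with
known planted structure. The pipeline covers:

- **Table I/O** (`mgnet.tables`) — feature-by-sample count/relative tables
  (TSV with a `#FeatureID` header, BIOM-JSON read-only), sample metadata
  (condition / genotype / negative-control flag), taxonomy maps, newick
  trees, and gene–taxon network export (TSV edge list + GraphML).
- **Synthetic data** (`mgnet.simulate`) — NB gene counts with condition
  fold changes, logistic-normal + multinomial OTU counts with planted
  basis correlations, contaminants enriched in blank controls, and
  gene–taxon links planted at a requested Spearman strength via a
  calibrated coupling coefficient. Fully deterministic under one seed.
- **Contaminant screening** (`mgnet.decontam`) — prevalence-based scores
  (one-sided Fisher exact p for "more prevalent in negative controls"),
  filtering at a classification threshold (default 0.1).
- **Diversity** (`mgnet.diversity`) — rarefaction (without replacement),
  resampled alpha diversity (Chao1 / observed OTUs / Shannon) with a
  Wilcoxon group test, Bray-Curtis and (un)weighted UniFrac distances,
  classical PCoA, and permutation PERMANOVA.
- **Differential abundance** (`mgnet.abundance`) — taxonomic
  agglomeration with last-characterized-level fallback, the
  0.1%-relative-abundance prevalence filter, median-of-ratios size
  factors (with a poscounts fallback), a simplified NB GLM Wald test,
  an NB likelihood-ratio test across three genotype categories, a
  Wilcoxon test for relative-abundance (pathway-style) tables, and BH
  adjustment. The NB stage is a deliberately simplified stand-in for
  DESeq2 (moment dispersions shrunk toward a mean-dispersion trend; no
  Cox-Reid adjustment, no fold-change shrinkage, no outlier filtering).
- **Integration** (`mgnet.integrate`) — the gene selection cascade
  (FDR < 0.05, pathway membership, |log2FC| > 0.35), CLR transform,
  tie-aware gene-by-taxon Spearman screen (exact permutation null for
  small tie-free n), and Storey q-values.
- **SparCC networks** (`mgnet.sparcc`) — from-scratch SparCC basis
  correlations with iterative strong-pair exclusion, permutation
  pseudo-p-values, and assembly of the mixed gene–taxon network
  (gene–taxon edges at q < 0.1; taxon–taxon edges at |R| >= 0.1 and
  pseudo-p < 0.05).

## CLI

All subcommands accept `--log-level` and write a JSON run manifest next to
their outputs.

```bash
mgnet simulate --config cfg.yaml --seed 1 --out data/
mgnet decontam --otu data/otu.tsv --meta data/metadata.tsv --threshold 0.1 --out dec/
mgnet diversity alpha --otu dec/clean.tsv --meta data/metadata.tsv --metric chao1 --out div/
mgnet diversity permanova --otu dec/clean.tsv --meta data/metadata.tsv --metric bray_curtis --out div/
mgnet diffabund --table data/gene.tsv --meta data/metadata.tsv --test wald --out de.tsv
mgnet integrate --genes data/gene.tsv --de de.tsv --otu dec/clean.tsv \
    --taxonomy data/taxonomy.tsv --meta data/metadata.tsv \
    --gene-subset pathway_genes.txt --out pairs.tsv
mgnet sparcc --otu dec/clean.tsv --seed 5 --out sparcc.tsv
mgnet network --pairs pairs.tsv --sparcc sparcc.tsv --out net
```

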