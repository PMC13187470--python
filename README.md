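# popspec

Population-resolved microbiome inference on amplicon data: degenerate
population-resolving primer design, phylogenetic-placement assignment of
amplicon sequence variants (ASVs) to sub-genus populations ("MCs"),
ordination/permutation statistics for classifying nutrient-gradient
"specialist" populations, phylogenetic comparative tests of gene-content and
phenotype association, and detection of specialist-exclusive convergent gene
clades. A fully deterministic synthetic-data generator with known ground
truth drives every stage, so the whole pipeline is testable offline.

## Modules

| module | what it does |
|---|---|
| `popspec.simulate` | ground-truth-known synthetic trees, marker alignments, Dirichlet-multinomial ASV tables, gene presence/absence, Brownian phenotypes |
| `popspec.markers` | discriminating-SNP search, minimal-IUPAC degenerate consensus, exhaustive primer-pair enumeration (17-25 bp, product < 600 bp, no 3' cross-complementarity), population-resolution scoring |
| `popspec.assign` | reference-guided profile alignment of queries, joint neighbor-joining tree, parental-node >80 % majority assignment, per-population abundance aggregation |
| `popspec.enrichment` | Bray-Curtis, non-metric MDS (Kruskal stress-1), one-factor PERMANOVA, envfit vector fitting with permutation p, dual-marker specialist classification with a 1 % abundance floor |
| `popspec.phylo` | Brownian covariance, simulation-based phylogenetic ANOVA, Pagel's lambda signal test, binary phylogenetic GLMM (penalized quasi-likelihood), the per-gene signal-then-test workflow, median-dichotomized chi-square |
| `popspec.convergence` | ortholog-group prevalence filter (>= 50 %), specialist-exclusive convergent clade detection |
| `popspec.pathway` | denitrification-pathway completeness ((napA or narG) and (nirS or nirK) and norB and nosZ) |
| `popspec.pipeline` / `popspec.cli` | end-to-end driver with a machine-readable manifest and the `popspec` command |

## CLI

```sh
popspec simulate --out data/ --seed 1
popspec design-primers --alignment aln.fasta --groups groups.tsv --out pairs.tsv
popspec assign --ref ref.fasta --asv asv.fasta --counts counts.tsv --threshold 0.8 --out out/
popspec enrich --abundance mc_abundance.tsv --metadata metadata.tsv --out out/
popspec classify-specialists --taxonomic1 t1.tsv --taxonomic2 t2.tsv \
    --functional fun.tsv --metadata metadata.tsv --out calls.tsv
popspec phylanova --tree tree.nwk --trait trait.tsv --groups groups.tsv
popspec phylo-assoc --tree tree.nwk --pa pa.tsv --labels labels.tsv --out assoc.tsv
popspec convergence --trees trees/ --mc-map map.tsv --specialists MC1,MC6 --out calls.tsv
popspec pathway --flags flags.tsv
popspec run --out run1/ --seed 1        # full synthetic pipeline
```

Exit codes: 0 ok, 1 user/input error, 2 internal error. All file formats are
plain text (FASTA, newick, TSV, JSON); coordinates in user-facing files are
1-based inclusive.

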