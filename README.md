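# synmut

Does per-gene synonymous diversity in natural isolates predict where
synonymous substitutions accumulate in an evolution experiment?  `synmut`
is a tested pipeline for asking that question: it annotates point
mutations from evolved clones codon-aware against an ancestral genome,
estimates per-gene synonymous nucleotide diversity (θ_s) from
natural-isolate codon alignments, compares the observed distribution of
synonymous substitutions over the θ_s-ranked gene axis against
gene-length-proportional and θ_s-proportional rate models with
Kolmogorov–Smirnov tests (asymptotic and Monte-Carlo), summarizes
mutation spectra per clone, and runs the expression/length association
analyses (Welch's t, Wilcoxon rank-sum, Pearson r, partial Kendall rank
correlation).  A synthetic-data generator produces ground-truth-labeled
cohorts so every stage is testable without downloads.

## Modules

| module | purpose |
|---|---|
| `synmut.codon_model` | genetic code (table 11), substitution effects, Nei–Gojobori synonymous-site counting, strand-collapsed spectrum classes |
| `synmut.diversity` | Watterson-style θ_s restricted to synonymous sites, from per-gene multi-FASTA alignments or a precomputed table |
| `synmut.mutation_annotation` | FASTA/GFF3 loading, VCF/TSV mutation reading, codon- and strand-aware effect annotation, core-genome filtering |
| `synmut.hypothesis_tests` | per-gene rate models, cumulative curves, KS comparisons, multinomial Monte-Carlo p-values, lineage subgroup tests, spectrum summaries |
| `synmut.association_stats` | presence/absence grouping, Welch's t, Wilcoxon rank-sum, Pearson r, Kendall tau-b, partial Kendall tau controlling for length |
| `synmut.synthetic_data` | seeded generators for gene sets, genomes, isolate alignments and mutation cohorts, with exact ground-truth bookkeeping |
| `synmut.cli_io` | YAML-configured pipeline orchestration and the `synmut` CLI |

## CLI

```sh
# generate a complete synthetic cohort (genome, GFF3, per-clone VCFs,
# theta and expression tables, ground truth)
synmut simulate --out cohort/ --seed 1

# run the whole analysis from a config
synmut run --config config.yaml --seed 1 --mc-reps 10000

# individual stages
synmut theta --alignments alns/ --out theta.tsv
synmut annotate --genome genome.fasta --features genes.gff3 \
    --mutations vcfs/ --core-genes core.txt --out annotated/
synmut assoc --counts per_gene.tsv --expression expr.tsv --out report.tsv
```

A minimal `config.yaml`:

```yaml
genome: cohort/genome.fasta
features: cohort/features.gff3
mutations: cohort           # directory of VCFs, a single VCF, or a TSV
clones: cohort/clones.tsv   # clone_id -> lineage_class
theta_table: cohort/theta.tsv   # or: alignments: <dir of per-gene FASTAs>
expression: cohort/expression.tsv
core_genes: cohort/core_genes.txt
out_dir: results
seed: 1
```

Outputs land under `out_dir`: `annotated_mutations.tsv`,
`per_gene_counts.tsv`, `ks_results.tsv`, per-mode cumulative curves,
`spectrum_by_clone.tsv`, `association_stats.tsv` and a `results.json`
summary.

## Conventions

* Coordinates are 1-based inclusive on disk (GFF3, VCF, TSVs) and 0-based
  half-open internally; `codon_index` and `codon_position` are 1-based.
* θ_s is Watterson's estimator on synonymous sites: S_syn / (a_n · L_syn).
  Columns count as synonymous segregating sites only when amino-acid
  identity is preserved across all sequences; codon columns containing
  gaps or ambiguity codes are dropped from both S and L.
* Spectrum classes are strand-collapsed (six classes: two transitions,
  four transversions).
* Every stochastic operation takes an explicit seed; cohort generation is
  byte-deterministic given parameters and seed.

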