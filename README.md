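# mytaxa

Weighted maximum-likelihood taxonomic classification of genomic and
metagenomic sequences, with AAI-based calling of novel taxa.

The framework has two halves:

* **Offline builder** — clusters reference protein-coding genes by
  reciprocal-best-match (RBM) graph components (identity > 40%, coverage of
  the shorter gene ≥ 70%, e-value < 1e-12; non-RBM paralogs merged into
  their best-match cluster), computes genome-aggregate **AAI** (arithmetic
  mean identity over RBM pairs) and the AAI distance tree, and derives two
  per-cluster, per-rank weights for phylum / genus / species:
  * **D** — discriminative power of sequence identity, from Gaussian KDEs
    (Scott's-rule bandwidths) of intra- vs inter-taxon pairwise identities;
  * **M** — agreement of the gene's phylogeny with the species (AAI) tree,
    as the fraction of concordant genome triplets (exhaustive up to 5000
    members, seeded Monte-Carlo above).
* **Online classifier** — maps query-gene hits (BLAST outfmt-6 TSV + GFF3
  gene calls) onto the clusters, keeps the top N = 5 hits per gene, scores
  each candidate taxon by `bitscore × (w_D·D(identity) + w_M·M)`, normalizes
  to likelihoods, and descends phylum → genus → species accepting the top
  candidate while its likelihood ≥ 0.5.  When the descent stops early, the
  best-match AAI decides the novelty rank: ≥ 95% known species, 60–95%
  novel species, 45–60% novel genus, < 45% a novel phylum-level lineage.

Everything is testable offline: `mytaxa.simulate` generates reference sets
with planted taxonomy, AAI band structure, HGT, and mock metagenome
fragments (per-base error model) together with full ground truth.

## CLI

```sh
# self-contained synthetic fixture set
mytaxa simulate --preset small --seed 42 --out fixtures/

# offline: cluster + weigh the reference
mytaxa build-db --genes fixtures/reference.faa --gene-map fixtures/gene_map.tsv \
    --matches fixtures/matches.tsv --taxonomy fixtures/taxonomy.tsv --out weightdb/

# online: classify query contigs
mytaxa classify --gff fixtures/fragments.gff3 --hits fixtures/hits.tsv \
    --db weightdb/ --taxonomy fixtures/taxonomy.tsv \
    --score-cutoff 0.5 --top-n 5 --out results.tsv --krona krona.xml

# benchmarking
mytaxa evaluate --results results.tsv --truth fixtures/truth.tsv \
    --taxonomy fixtures/taxonomy.tsv --out metrics.tsv
mytaxa optimize-weights --gff fixtures/fragments.gff3 --hits fixtures/hits.tsv \
    --db weightdb/ --taxonomy fixtures/taxonomy.tsv --truth fixtures/truth.tsv \
    --seed 0 --out wd_table.tsv
```

Logs go to stderr, results to files only; every command writes a
`run_manifest.json` with its parameters and seeds.

## Layout

| module | role |
| --- | --- |
| `mytaxa.clustering` | ortholog filter, RBM edges, components, paralog merge |
| `mytaxa.aai` | AAI matrix, species tree, rank bands, novelty calls |
| `mytaxa.weights` | D (KDE) and M (triplet concordance) weights |
| `mytaxa.pipeline` | offline build orchestration |
| `mytaxa.classifier` | top-N scoring, rank descent, novelty attachment |
| `mytaxa.evaluation` | TP/WP/FN/FP/TN, Sn/Sp, w_D grid search, benchmarks |
| `mytaxa.simulate` | synthetic references, metagenomes, hit tables |
| `mytaxa.io` | FASTA / GFF3 / outfmt-6 / taxonomy TSV / Krona XML / weight DB |
| `mytaxa.cli` | `mytaxa` entry point |
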