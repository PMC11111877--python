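# funcmod

Multi-omics function-module discovery and lineage-plasticity scoring as a
reusable, fully synthetic-testable pipeline:

- **Hypergeometric enrichment** of per-omics gene sets against a term
  database, with exact tail probabilities, Benjamini–Hochberg q-values, and
  p/q filtering (`funcmod.enrichment`).
- **Function-module clustering**: Cohen's kappa agreement between enriched
  terms' gene-membership vectors, bottom-up neighbor joining on the
  1 − kappa distance, and a longest-internal-branch tree cut into K modules
  with per-source composition summaries (`funcmod.clustering`).
- **Sample scoring**: single-sample GSEA (rank-weighted ECDF integral,
  min–max normalized), Pearson gene–trait correlation with positive-value
  retention, and preranked GSEA with a gene-label permutation null and
  leading-edge extraction, composed into an end-to-end plasticity procedure
  (`funcmod.scoring`).
- **CNV/SNV analyses**: copy-number categorization via CN = 2^(Segment+1)
  with exact boundary thresholds, chi-square and Kruskal–Wallis association
  tests (with a Monte-Carlo guard for sparse tables), dominant-type
  prevalence, hypergeometric mutation-stratum enrichment, and Gleason /
  T-stage clinical mappings (`funcmod.cnv`).
- **Linear risk scoring** with the published five-covariate coefficients and
  threshold shipped as defaults, plus Harrell's concordance index
  (`funcmod.survival`).
- **TF activity**: knockdown-signature over-representation of a target gene
  list, and regulon-based activity from a signed rank-mean statistic with an
  empirical permutation null (`funcmod.tf`).
- **Synthetic data** with planted structure for every stage — term blocks
  with a configurable within-block Jaccard floor, expression with a shifted
  sample subgroup, planted CNV amplifications/deletions, a stratum-enriched
  mutation, proportional-hazards survival times, and one planted active TF —
  all ground truths emitted alongside the data (`funcmod.synthetic`).
- **Pipeline orchestration** with file-only stage handoffs and a
  sha256-checksummed manifest; identical config + seed reproduces identical
  checksums (`funcmod.pipeline`).

## CLI

All stages are exposed under a single `funcmod` entry point:

```bash
# generate every synthetic input (with ground truth) for seed 7
funcmod simulate --seed 7 --outdir sim/

# hypergeometric enrichment of one omics set
funcmod enrich --query sim/source_CNV.tsv --terms sim/terms.gmt \
    --universe sim/universe.txt --alpha-p 0.05 --alpha-q 0.05 --out enr_CNV.tsv

# kappa -> neighbor joining -> 6 modules
funcmod cluster --enrichment-tables enr_*.tsv --terms sim/terms.gmt \
    --universe sim/universe.txt --k 6 --outdir modules/

# sample scoring
funcmod score ssgsea --expr sim/expression.tsv --gene-set genes.tsv --out scores.tsv
funcmod score gsea --signature sig.tsv --gene-set genes.tsv --n-perm 1000 --seed 1 --out gsea.json

# CNV / SNV
funcmod cnv categorize --segments sim/segments.tsv --out cats.tsv
funcmod cnv test --categories cats.tsv --clinical sim/clinical.tsv --out tests.tsv
funcmod snv enrich --mutations sim/mutations.tsv --clinical sim/clinical.tsv \
    --gene G00020 --stratum A

# risk score and concordance
funcmod risk score --expr sim/risk_covariates.tsv --out risk.tsv
funcmod risk cindex --scores risk.tsv --survival sim/survival.tsv

# TF activity
funcmod tf activity --regulons sim/regulons.gmt --signature sim/signature.tsv \
    --n-perm 1000 --seed 1 --out activity.tsv

# everything at once, driven by one YAML config
funcmod pipeline run --config cfg.yaml
```

A minimal pipeline config:

```yaml
seed: 7
outdir: out
simulate:            # omit and provide paths.indir to use existing inputs
  n_genes: 1000
  n_terms: 60
  n_blocks: 6
  n_samples: 100
params:
  k: 6
  n_perm: 200
```

## File formats

Universe: one gene per line. Gene sets and term databases: GMT. Regulons:
GMT with `GENE:+1` / `GENE:-1` mode suffixes. Matrices (expression,
segments, mutations, covariates): genes × samples TSV with a sample-id
header row. Survival/clinical: TSV with `sample`, `time`, `event` (plus
covariates or `group`/`stratum`). Ground truth and manifests: JSON.
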