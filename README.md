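# svgex

Integrative analysis of somatic structural variant (SSV) breakpoints and
gene expression in tumor cohorts: per-gene breakpoint predictors,
covariate-adjusted association models with two FDR procedures,
TAD-disruption and enhancer-translocation annotation, fusion-call
refinement with WGS support, SSV-burden correlates, and pathway-level
alteration tabulation — together with a synthetic cohort generator that
makes every stage testable without any external data.

## Components

| Module | What it does |
| --- | --- |
| `svgex.io_formats` | Readers/writers: SV VCF (BND mate pairing), BEDPE, TSV matrices, BED, tumor metadata, fusion/mutation tables; quantile normalization. Internal coordinates are 0-based half-open. |
| `svgex.breakpoint_matrices` | Gene x tumor predictors: binary window-presence matrices (gene body, 100 kb up/downstream, symmetric) and the log2 nearest-breakend distance matrix (±1 Mb, imputed at 1 Mb). |
| `svgex.cis_association` | Per-gene OLS of log2 expression on a breakpoint predictor with tumor-type and thresholded-CNA covariates; direct `p·N/#{p'≤p}` FDR; stratified-permutation FDR; subgroup breakpoint enrichment. |
| `svgex.regulatory_context` | TAD-disruption classification, enhancer-translocation detection from breakend orientation, CNA-breakpoint and TAD enrichment tests. |
| `svgex.fusion_refinement` | Banned-list/same-gene filtering, gene-body SSV support, high-expression rules, fusion tiering. |
| `svgex.burden_analysis` | Per-tumor SSV burden and its expression, mutation, group, and paired initial-vs-recurrent correlates; generic gene-set Fisher test. |
| `svgex.pathway_catalog` | Per-(tumor, gene) alteration calls with precedence `snv_indel > fusion > deep_deletion > amplification > ssv_cis`; pathway matrices and type enrichment. Ships an editable pathway/role catalog (`svgex/data/pathways.yaml`). |
| `svgex.synthetic_cohort` | Seeded cohort generator with planted cis-effect genes, CNA-dosage confounders, fusions, burden drivers, and a ground-truth manifest. |

## CLI

All stages are exposed through one entry point:

```sh
svgex simulate --seed 1 --out cohort/            # synthetic input bundle + truth.json
svgex build-matrices --sv cohort/sv.bedpe --genes cohort/genes.bed \
      --meta cohort/meta.tsv --windows body --windows dist1mb --out-prefix mat
svgex associate --sv cohort/sv.bedpe --genes cohort/genes.bed \
      --expr cohort/expression.tsv --cna cohort/cna.tsv --meta cohort/meta.tsv \
      --window dist1mb --fdr both --n-perm 200 --seed 1 --out assoc.tsv
svgex annotate-regulatory --sv cohort/sv.bedpe --genes cohort/genes.bed \
      --tads cohort/tads.bed --enhancers cohort/enhancers.bed \
      --assoc assoc.tsv --expr cohort/expression.tsv --out-prefix reg
svgex refine-fusions --calls cohort/fusions.tsv --banned cohort/banned.tsv \
      --sv cohort/sv.bedpe --genes cohort/genes.bed \
      --expr cohort/expression.tsv --out fusions_refined.tsv
svgex burden --sv cohort/sv.bedpe --meta cohort/meta.tsv \
      --expr cohort/expression.tsv --mut cohort/mutations.tsv --out-prefix burden
svgex pathways --sv cohort/sv.bedpe --genes cohort/genes.bed \
      --expr cohort/expression.tsv --cna cohort/cna.tsv --meta cohort/meta.tsv \
      --mut cohort/mutations.tsv --assoc-dist assoc.tsv --out-prefix pw
```

SV input is accepted as BEDPE (multi-tumor) or as a per-tumor Manta-style
VCF (`--tumor-id` required); BND mate pairs are merged so each
translocation counts once.

## Conventions

- Expression models use `log2(x + 1)`; burden models use `log10(count + 1)`.
- Distance-matrix cells are `log2` distances clipped below at 1 bp and
  capped/imputed at `log2(1e6)`.
- Breakend orientation records the retained side of a junction:
  `positive` keeps the upstream (lower-coordinate) side, `negative` the
  downstream side; BEDPE strand columns encode the same (`+`/`-`).
- The direction of a log-distance association is reported as `positive`
  when closer breakpoints associate with higher expression (negative
  coefficient).
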