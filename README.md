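# tracegene

Tissue-aware machine learning for prioritizing genes that underlie
**tissue-selective Mendelian diseases** — diseases whose clinical
manifestation is confined to specific tissues even when the causal gene is
broadly expressed. The package is aimed at computational geneticists and
rare-disease researchers who want to (i) score every protein-coding gene's
risk of underlying a disease that manifests in a given tissue, (ii)
understand *why* a gene scores high, and (iii) shortlist the candidate
genes that remain after variant filtering in a patient's exome.

## The method

From multi-omics inputs (a gene × sample count matrix with a sample→tissue
map, a developmental organ × timepoint panel, a PPI network, GO
annotations, paralog pairs and tissue eQTL q-values) the package engineers
an annotated gene × feature table. Per tissue *t* the transcriptomic core
is the median normalized expression med *e*<sub>gt</sub> and the
preferential expression

&nbsp;&nbsp;&nbsp;&nbsp;pref<sub>gt</sub> = (med *e*<sub>gt</sub> −
median<sub>t′</sub> med *e*<sub>gt′</sub>) / IQR<sub>t′</sub>(med *e*<sub>gt′</sub>),

complemented by tissue-interactome degree features, tissue-differential PPI
summaries, node2vec interactome embeddings (64 dimensions per interactome),
differential GO-process activities (mean log2 fold-change of a term's
member genes), paralog dosage ratios, eQTL q-values and developmental
variability. Missing cells are imputed by chained Bayesian-ridge
regressions, expression features are symmetrized (Yeo-Johnson), and every
feature is scaled to [−1, 1].

Per tissue, a two-layer stack scores each gene: five base learners
(XGBoost, random forest, logistic regression, logistic-initialized gradient
boosting, and an MLP; L1-SVM feature selection for the first three) feed a
neural meta-learner through min-max-scaled 0–10 scores, evaluated with
strictly out-of-fold stratified 10-fold cross-validation (AUC / auPRC).
Shapley additive attributions of the boosted-tree models, normalized and
aggregated by feature family and tissue of origin, explain the
predictions. For a patient, the candidate genes are entirely withheld —
imputation, transforms, scaling, feature selection and all models are
fitted on non-candidate genes only — then scored and ranked.

Because the original data sources (GTEx, OMIM, curated disease–tissue
maps, interactome databases) are not redistributable here, the package
ships a synthetic-cohort generator that emulates their statistical
structure with planted, mechanism-labeled signal; every stage is tested
end to end against it.

## Worked example

```python
from tracegene import (
    CohortConfig, generate_cohort, build_feature_table,
    TracePreprocessor, trace_cross_validate, evaluate,
)
from tracegene.pipeline import cohort_labels

cfg = CohortConfig(n_genes=1500, tissues=("liver", "brain", "skin"),
                   samples_per_tissue=10, positives_per_tissue=60,
                   frac_disease_genes=0.2, seed=2)
bundle = generate_cohort(cfg)                      # counts, PPIs, GO, eQTL, labels
table, ctx = build_feature_table(bundle, seed=2)   # gene x feature table
processed = TracePreprocessor(seed=2).fit_transform(table)
labels = cohort_labels(bundle, processed.genes)

cv = trace_cross_validate(processed.values, labels["liver"].labels, seed=2)
print(f"features: {table.values.shape}")
print(f"meta AUC {cv.metrics['meta']['auc_pooled']:.3f}")
print(evaluate(cv.trace_scores, labels["liver"].labels, labels["liver"].groups))
```

prints (seed-reproducible):

```
features: (1244, 364)
meta AUC 0.972
{'auc': 0.9721..., 'auprc': 0.7500..., 'prevalence': 0.0426...,
 'mw_p_vs_non_disease': 2.62e-31, 'mw_p_vs_other_disease': 1.00e-26}
```

1,244 of the 1,500 simulated genes survive the expression filters; 364
features is the closed-form count for 3 tissues (3·21 per-tissue features
+ 3 eQTL columns + 64·4 embedding dimensions + 35 developmental cells + 7
developmental-variability organs). The meta AUC of 0.97 says the
stack recovers the planted tissue signal; the Mann–Whitney p-values say the
planted liver disease genes score far above both non-disease genes and
disease genes of other tissues. The same workflow is available from the
shell via the `tracegene` CLI (`simulate`, `build-features`, `preprocess`,
`train`, `explain`, `rank-patient`, `benchmark`).

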