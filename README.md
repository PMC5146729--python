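# inflamscore

Composite inflammatory-transcriptome scores and life-course socioeconomic
association models for blood gene-expression data.

## The problem

Low socioeconomic position (SEP) — especially in early life — is associated
with a lasting up-regulation of inflammation-related gene expression in
adult blood. Testing hundreds of inflammatory genes one at a time against a
binary SEP indicator is underpowered in cohort-scale microarray studies, so
the analysis this package implements condenses a curated inflammatory gene
panel (with 17 functional sub-pathways) into per-sample composite scores and
models those against SEP measured at three life stages: father's occupation
(early life), own education (young adulthood), and highest household
occupation (adulthood), each dichotomised with the high/non-manual class as
reference.

`inflamscore` is a library for epidemiologists and computational biologists
who want to apply or scrutinise this design: it provides the scores, the
technical de-noising, the sequentially adjusted life-course models, a
random-gene-set specificity null, signature-based cell-type deconvolution,
a replication path for GEO-format public data, and a synthetic cohort
generator that plants known truth for every stage.

## The model

Per-gene expression follows a linear mixed model

    Y_i = α + β₁ X_i + FE_i β₂ + u_iso(i) + u_hyb(i) + u_lab(i) + ε_i

where `Y_i` is a gene's log2 expression in participant `i`, `X_i` the binary
SEP indicator (positive β₁ = higher expression in the low SEP group), `FE_i`
the fixed covariates (age, gender, centre, phase, two case-control
indicators), and `u` crossed random intercepts for the RNA isolation,
hybridization and labeling batches, estimated by REML. *De-noised*
expression subtracts only the predicted random intercepts.

From the de-noised panel three composite scores are built per sample:

* **quartile score** — the count of panel genes expressed strictly above
  their cross-sample 75th percentile (type-7 quantile);
* **PC1 score** — the first principal component of the standardized panel;
* **rank score** — the median of the sample's per-gene ranks, each gene
  oriented by the sign of its SEP association.

Scores are regressed on SEP through a nested ladder: model A (design
covariates + early-life SEP), B (+ education), C (+ household occupation),
D (+ BMI, smoking, alcohol) and a fully adjusted model (+ estimated
neutrophil and monocyte proportions from least-squares deconvolution).
Specificity of the panel is quantified by the fraction of random same-size
gene sets whose association p-value beats the observed one; per-gene
multiple testing uses the PCA-based effective number of tests
(α = 0.05 / k, with k the components explaining 95% of panel variance).

## Worked example

`examples/03_life_course_models.py` simulates a 250-sample cohort with a
planted early-life SEP effect on a 300-gene panel, computes the quartile
score, and fits the ladder:

```
        beta     se  pvalue    n
model
A      8.234  1.307     0.0  203
B      7.964  1.531     0.0  203
C      7.970  1.534     0.0  203
D      6.670  1.245     0.0  203
```

The early-life SEP coefficient is in score counts: low-SEP participants
express ~8 more panel genes above their upper quartile than high-SEP
participants, and the contrast survives adjustment for later-life SEP (B, C)
and behavioural covariates (D) — the life-course signature the design looks
for. `n` is the shared complete-case analysis set (missing SEP
questionnaire items are generated too).

The other examples walk through cohort simulation (`01`), collapsing /
de-noising / scoring (`02`), the specificity null (`04`), deconvolution and
the fully adjusted model (`05`), and the GEO replication path (`06`). A thin
CLI covers the shell-level entry points: `inflamscore simulate`,
`inflamscore run-full`, `inflamscore replicate`.

## Layout

```
src/inflamscore/   cohort, annotation, preprocess, scores, association,
                   specificity, deconvolution, geo, pipeline, cli
examples/          one narrative script per capability
tests/             pytest suite (unit, property and acceptance tests)
docs/methods.md    modelling assumptions, parameter choices, limitations
```
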