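"""Sequentially adjusted life-course models of the composite score.

Model A adjusts the early-life SEP contrast for design covariates; B and C
add the later-life SEP indicators; D adds behavioural covariates.  A
positive coefficient means a higher inflammatory score in the low SEP group.
Because later SEP indicators are on the causal path of early-life SEP, an
early-life effect that survives B and C is the life-course signal of
interest.
"""

import inflamscore as im

cohort = im.generate_cohort(im.CohortConfig(
    n_samples=250, n_genes=1000, n_inflammatory=300, seed=3))
expr = im.collapse_probes(cohort.expression, cohort.probe_to_gene)
panel, _ = im.select_inflammatory(expr, cohort.gene_list)
score = im.quartile_score(panel)

ladder = im.life_course_ladder(score, cohort.metadata, sep="sep_early",
                               models=("A", "B", "C", "D"))
print(ladder[["beta", "se", "pvalue", "n"]].round(3))
print("\nThe early-life SEP coefficient (score counts) is stable across the"
      "\nladder: the planted effect acts directly, not through later SEP.")

# descriptive group comparison, chi-squared / t-test conventions
summary = im.table1(cohort.metadata, group="sep_early")
print("\nDescriptive comparison by early-life SEP (first rows):")
print(summary.head(6).to_string(index=False))
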