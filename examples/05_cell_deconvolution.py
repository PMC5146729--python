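"""Cell-type deconvolution and the fully adjusted model.

Least-squares deconvolution over a 17-type blood signature, iteratively
removing negative coefficients and renormalizing; fine types aggregate to
Lymphocytes / Neutrophils / Monocytes, whose estimated proportions enter the
fully adjusted score model to rule out cell-composition confounding.
"""

import inflamscore as im

cohort = im.generate_cohort(im.CohortConfig(
    n_samples=200, n_genes=1000, n_inflammatory=300, seed=5))
expr = im.collapse_probes(cohort.expression, cohort.probe_to_gene)

props = im.estimate_proportions(expr, cohort.signature)
print("mean estimated coarse composition:")
print((100 * props.coarse.mean()).round(1).astype(str) + " %")

meta = cohort.metadata.copy()
meta["prop_neutrophils"] = props.coarse["Neutrophils"]
meta["prop_monocytes"] = props.coarse["Monocytes"]

panel, _ = im.select_inflammatory(expr, cohort.gene_list)
score = im.quartile_score(panel)
for model in ("D", "fully_adjusted"):
    r = im.score_association(score, meta, sep="sep_early", model=model)
    print(f"model {model:>14}: beta = {r.beta:6.2f} (SE {r.se:.2f}), "
          f"p = {r.pvalue:.3f}, n = {r.n}")
print("\nA stable coefficient after adding the cell proportions indicates "
      "the SEP signal is not driven by blood cell composition.")
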