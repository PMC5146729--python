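"""Replication path on an external GEO-format dataset.

Builds a small synthetic series-matrix file with a planted early-life SEP
effect (30 low / 30 high SEP samples), then runs the replication pipeline:
quantile normalization, probe collapsing, panel intersection, the three
composite scores, and an unadjusted regression on the derived SEP indicator.
For a real accession, point the same call at the downloaded series matrix
and its platform annotation.
"""

import pathlib
import sys
import tempfile

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "tests"))
from conftest import make_geo_fixture  # noqa: E402  (fixture builder)

from inflamscore.pipeline import run_replication  # noqa: E402

with tempfile.TemporaryDirectory() as tmp:
    fix = make_geo_fixture(tmp, seed=6, n_samples=60, planted_shift=0.4)
    res = run_replication(fix["series_matrix"], fix["annotation"],
                          fix["gene_list"], "early life ses",
                          ["low"], ["high"])

print(f"panel coverage: {res['coverage']:.1%} "
      f"({res['n_panel_genes']} genes measured)")
for outcome, r in res["unadjusted"].items():
    print(f"{outcome:>14}: beta = {r.beta:7.2f} (SE {r.se:.2f}), "
          f"p = {r.pvalue:.2g}, n = {r.n}")
print("\nPositive quartile/rank coefficients recover the planted upward "
      "shift\nof panel expression in the low early-life SEP group.")
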