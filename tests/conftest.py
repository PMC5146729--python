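import numpy as np
import pandas as pd
import pytest

from inflamscore import CohortConfig, collapse_probes, generate_cohort


@pytest.fixture(scope="session")
def clean_config():
    """Batch-free, confounder-free configuration: expression is exactly
    gene baseline + SEP shift + Gaussian noise, so analytic truths hold."""
    return CohortConfig(
        n_samples=120, n_genes=400, n_inflammatory=80,
        probes_per_gene_mean=1.0, effect_delta=0.4,
        batch_sd=(0.0, 0.0, 0.0), noise_sd=0.5, cell_effect_sd=0.0,
        confounder_effects={}, sep_missing=(0.0, 0.0, 0.0), seed=7,
    )


@pytest.fixture(scope="session")
def clean_cohort(clean_config):
    return generate_cohort(clean_config)


@pytest.fixture(scope="session")
def clean_gene_expr(clean_cohort):
    return collapse_probes(clean_cohort.expression, clean_cohort.probe_to_gene)


@pytest.fixture(scope="session")
def batch_cohort():
    """Small cohort with realistic technical batch structure for the
    mixed-model paths (kept small: each REML fit is ~0.1 s)."""
    cfg = CohortConfig(
        n_samples=120, n_genes=40, n_inflammatory=20,
        probes_per_gene_mean=1.0, effect_delta=0.3,
        noise_sd=0.5, sep_missing=(0.0, 0.0, 0.0), seed=3,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def batch_gene_expr(batch_cohort):
    return collapse_probes(batch_cohort.expression, batch_cohort.probe_to_gene)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def make_geo_fixture(outdir, seed=3, n_samples=60, planted_shift=0.4):
    """Synthetic GEO-format replication fixture: a series-matrix file and a
    SOFT platform annotation with a planted early-life SEP effect on the
    first 100 panel genes (30 low / 30 high SEP samples)."""
    import os

    from inflamscore import GeneList
    from inflamscore.geo import write_series_matrix

    rng_f = np.random.default_rng(seed)
    n_probe, n_gene = 300, 250
    sep = np.array([1] * (n_samples // 2) + [0] * (n_samples - n_samples // 2))
    genes = [f"GENE{i:03d}" for i in range(n_gene)]
    probe_ids = [f"ILMN_{i:06d}" for i in range(n_probe)]
    # every gene gets one probe; the surplus probes land on random genes
    p2g_idx = np.concatenate([np.arange(n_gene),
                              rng_f.integers(0, n_gene, n_probe - n_gene)])
    base = rng_f.normal(8, 1, n_gene)
    vals = base[p2g_idx][:, None] + rng_f.normal(0, 0.5, (n_probe, n_samples))
    vals[p2g_idx < 100] += planted_shift * sep
    expr = pd.DataFrame(vals, index=probe_ids,
                        columns=[f"GSM{i:05d}" for i in range(n_samples)])
    chars = pd.DataFrame(
        {"early life ses": np.where(sep == 1, "low", "high")},
        index=expr.columns)
    sm_path = os.path.join(outdir, "series_matrix.txt")
    write_series_matrix(sm_path, expr, chars)
    ann_path = os.path.join(outdir, "platform.txt")
    with open(ann_path, "w") as fh:
        fh.write("#synthetic platform annotation\n!platform_table_begin\n")
        fh.write("ID\tSymbol\n")
        for p, gi in zip(probe_ids, p2g_idx):
            fh.write(f"{p}\t{genes[gi]}\n")
        fh.write("!platform_table_end\n")
    gene_list = GeneList(genes=genes[:100] + ["ABSENT1", "ABSENT2"],
                         subpathway={}, universe=set(genes))
    return {"series_matrix": sm_path, "annotation": ann_path,
            "gene_list": gene_list, "sep": sep, "shift": planted_shift}


def random_expression(rng, n_genes=10, n_samples=20, prefix="g"):
    vals = rng.normal(7.0, 1.0, size=(n_genes, n_samples))
    return pd.DataFrame(
        vals,
        index=[f"{prefix}{i:03d}" for i in range(n_genes)],
        columns=[f"s{j:03d}" for j in range(n_samples)],
    )
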