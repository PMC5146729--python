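"""Synthetic blood-transcriptome cohort generator.

Emulates the data structure of a case-control microarray study of life-course
socioeconomic position (SEP): probe-level log2 expression with crossed
technical batch effects (RNA isolation, hybridization, labeling), three
correlated binary SEP indicators ordered in time (father's occupation,
own education, household occupation), questionnaire covariates that confound
the SEP-expression relationship, a curated inflammatory gene panel split into
functional sub-pathways, and latent blood cell-type composition.

Everything is generated from a single seed and is bit-reproducible.  The
generator records its ground truth (which probe is the most variable one per
gene, the true cell proportions, the injected effect size) so downstream
stages can be tested against planted answers.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .annotation import GeneList
from .deconvolution import SignatureMatrix

__all__ = [
    "CohortConfig",
    "Cohort",
    "generate_cohort",
    "generate_gene_list",
    "generate_signature",
    "expected_quartile_shift",
    "calibrate_effect_delta",
    "SUBPATHWAY_NAMES",
    "CELL_TYPES",
    "COARSE_MAP",
]

# Functional sub-pathway names of the curated inflammatory panel, with the
# panel's gene counts (sum = 845).  Used verbatim when the configuration asks
# for the canonical 17-way split; otherwise sizes are rescaled.
SUBPATHWAY_NAMES: tuple[str, ...] = (
    "Cytokine signaling",
    "MAPK signaling",
    "Adhesion-Extravasation-Migration",
    "Leukocyte signaling",
    "Apoptosis signaling",
    "Phagocytosis-Ag presentation",
    "G-Protein Coupled Receptor signaling",
    "Innate pathogen detection",
    "PI3K/AKT signaling",
    "Eicosanoid signaling",
    "NF-kB signaling",
    "TNF superfamily signaling",
    "Natural killer cell signaling",
    "Complement cascade",
    "ROS/Glutathione/Cytotoxic granules",
    "Glucocorticoid/PPAR signaling",
    "Calcium signaling",
)
SUBPATHWAY_SIZES_845: tuple[int, ...] = (
    119, 111, 110, 103, 64, 37, 34, 34, 34, 32, 32, 31, 29, 27, 18, 17, 13,
)

# Fine blood cell panel (17 types) and its aggregation to the three
# complete-blood-count classes.
CELL_TYPES: tuple[str, ...] = (
    "B cells naive", "B cells memory", "Plasma cells",
    "T cells CD4 naive", "T cells CD4 memory", "T cells CD8",
    "T cells gamma delta", "NK cells resting", "NK cells activated",
    "Monocytes classical", "Monocytes non-classical",
    "Dendritic cells resting", "Dendritic cells activated",
    "Neutrophils", "Eosinophils", "Basophils", "Mast cells",
)
COARSE_MAP: dict[str, str] = {
    "B cells naive": "Lymphocytes", "B cells memory": "Lymphocytes",
    "Plasma cells": "Lymphocytes", "T cells CD4 naive": "Lymphocytes",
    "T cells CD4 memory": "Lymphocytes", "T cells CD8": "Lymphocytes",
    "T cells gamma delta": "Lymphocytes", "NK cells resting": "Lymphocytes",
    "NK cells activated": "Lymphocytes",
    "Monocytes classical": "Monocytes", "Monocytes non-classical": "Monocytes",
    "Dendritic cells resting": "Monocytes", "Dendritic cells activated": "Monocytes",
    "Neutrophils": "Neutrophils", "Eosinophils": "Neutrophils",
    "Basophils": "Neutrophils", "Mast cells": "Neutrophils",
}
# Mean coarse composition of peripheral blood mononuclear fractions used to
# scale the Dirichlet prior of the latent cell proportions.
_COARSE_TARGET = {"Lymphocytes": 0.75, "Neutrophils": 0.18, "Monocytes": 0.07}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of the synthetic cohort.

    Defaults emulate the cohort the pipeline is designed for: ~250 samples,
    ~15,000 annotated genes of which 845 belong to the inflammatory panel,
    a subtle upward shift of inflammatory-gene expression in the low
    early-life SEP group, and crossed technical batches.
    """

    n_samples: int = 250
    n_genes: int = 15000
    n_inflammatory: int = 845
    probes_per_gene_mean: float = 1.5
    #: standardized mean log2 shift of inflammatory genes in the low
    #: early-life SEP group; the default yields a composite-score contrast
    #: of roughly 20 counts over an 845-gene panel.
    effect_delta: float = 0.05
    batch_sd: tuple[float, float, float] = (0.20, 0.15, 0.10)
    noise_sd: float = 0.50
    #: marginal probability of the "low" class for early / young / adult SEP
    sep_prevalence: tuple[float, float, float] = (0.64, 0.56, 0.34)
    #: dependence between successive SEP indicators (0 = independent)
    sep_correlation: float = 0.45
    confounder_effects: Mapping[str, float] = field(
        default_factory=lambda: {"age": 0.003, "bmi": 0.005, "smoking_current": 0.05}
    )
    #: scale of the latent cell-composition contribution to expression
    cell_effect_sd: float = 0.10
    #: fraction of samples with a missing value per SEP indicator
    sep_missing: tuple[float, float, float] = (0.08, 0.004, 0.07)
    n_subpathways: int = 17
    n_cell_types: int = 17
    signature_genes_per_type: int = 10
    seed: int = 0

    def validate(self) -> None:
        if self.n_inflammatory > self.n_genes:
            raise ValueError(
                f"n_inflammatory ({self.n_inflammatory}) cannot exceed "
                f"n_genes ({self.n_genes})"
            )
        if self.probes_per_gene_mean < 1:
            raise ValueError("probes_per_gene_mean must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if any(s < 0 for s in self.batch_sd):
            raise ValueError("batch SDs must be non-negative")
        if not all(0 < p < 1 for p in self.sep_prevalence):
            raise ValueError("SEP prevalences must lie in (0, 1)")
        if not (0 <= self.sep_correlation < 1):
            raise ValueError("sep_correlation must lie in [0, 1)")
        if self.n_subpathways < 1:
            raise ValueError("n_subpathways must be >= 1")
        if self.n_cell_types < 3:
            raise ValueError("need at least 3 cell types")


@dataclass
class Cohort:
    """A generated cohort and its ground truth."""

    expression: pd.DataFrame        # probes x samples, log2 scale
    metadata: pd.DataFrame          # samples x covariates
    gene_list: GeneList
    signature: SignatureMatrix
    probe_to_gene: pd.Series        # probe id -> gene id
    planted_probe: pd.Series        # gene id -> its most variable probe id
    true_cell_props: pd.DataFrame   # samples x fine cell types (simplex rows)
    config: CohortConfig


def _markov_sep(rng: np.random.Generator, n: int,
                prevalence: tuple[float, float, float],
                corr: float) -> np.ndarray:
    """Three time-ordered binary SEP indicators as a Markov chain.

    Transition into the "low" class is ``p + corr * (1 - p)`` when the
    previous stage was low; the complementary transition is chosen so each
    stage keeps its target marginal prevalence (clipped to [0, 1] when the
    correlation requested is infeasible for the marginals).
    """
    sep = np.empty((n, 3), dtype=float)
    sep[:, 0] = rng.random(n) < prevalence[0]
    for k in (1, 2):
        p = prevalence[k]
        p_prev = prevalence[k - 1]
        p_low = p + corr * (1 - p)
        p_high = np.clip((p - p_prev * p_low) / (1 - p_prev), 0.0, 1.0)
        prob = np.where(sep[:, k - 1] == 1, p_low, p_high)
        sep[:, k] = rng.random(n) < prob
    return sep


def _subpathway_sizes(n_inflammatory: int, n_subpathways: int) -> list[int]:
    """Split the panel into sub-pathway sizes mimicking the curated panel.

    For the canonical 845-gene / 17-pathway configuration the exact published
    split is used; otherwise sizes are rescaled by largest remainder with a
    minimum of one gene per pathway.
    """
    if n_inflammatory == 845 and n_subpathways == 17:
        return list(SUBPATHWAY_SIZES_845)
    base = np.array(SUBPATHWAY_SIZES_845[:n_subpathways], dtype=float)
    if n_subpathways > 17:
        base = np.concatenate([base, np.full(n_subpathways - 17, 20.0)])
    share = base / base.sum() * n_inflammatory
    sizes = np.floor(share).astype(int)
    sizes = np.maximum(sizes, 1)
    # largest-remainder correction to hit the exact total
    while sizes.sum() > n_inflammatory:
        sizes[int(np.argmax(sizes))] -= 1
    rem = share - np.floor(share)
    order = np.argsort(-rem)
    i = 0
    while sizes.sum() < n_inflammatory:
        sizes[order[i % n_subpathways]] += 1
        i += 1
    return sizes.tolist()


def generate_gene_list(config: CohortConfig,
                       rng: np.random.Generator | None = None) -> GeneList:
    """Gene universe with an inflammatory panel partitioned into sub-pathways."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    width = max(5, len(str(config.n_genes)))
    universe = [f"G{i:0{width}d}" for i in range(config.n_genes)]
    chosen = rng.choice(config.n_genes, size=config.n_inflammatory, replace=False)
    chosen.sort()
    genes = [universe[i] for i in chosen]
    sizes = _subpathway_sizes(config.n_inflammatory, config.n_subpathways)
    if config.n_subpathways == 17:
        labels = list(SUBPATHWAY_NAMES)
    else:
        labels = [f"SP{j + 1:02d}" for j in range(config.n_subpathways)]
    subpathway: dict[str, str] = {}
    perm = rng.permutation(config.n_inflammatory)
    pos = 0
    for label, size in zip(labels, sizes):
        for idx in perm[pos:pos + size]:
            subpathway[genes[idx]] = label
        pos += size
    return GeneList(genes=genes, subpathway=subpathway, universe=set(universe))


def generate_signature(config: CohortConfig,
                       rng: np.random.Generator | None = None,
                       gene_ids: list[str] | None = None,
                       max_retries: int = 5) -> SignatureMatrix:
    """Non-negative reference expression profiles for the fine cell panel.

    Each cell type receives a disjoint block of marker genes boosted well
    above a log-normal background, which keeps the matrix far from rank
    deficiency; a bounded resampling loop guards the degenerate draw.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed + 7)
    k = config.n_cell_types
    types = list(CELL_TYPES[:k]) if k <= 17 else (
        list(CELL_TYPES) + [f"Cell type {j}" for j in range(18, k + 1)]
    )
    n_sig = config.signature_genes_per_type * k
    if gene_ids is None:
        gene_ids = [f"SIG{i:04d}" for i in range(n_sig)]
    if len(gene_ids) < k:
        raise ValueError("need at least as many signature genes as cell types")
    coarse = {t: COARSE_MAP.get(t, "Lymphocytes") for t in types}
    for _ in range(max_retries):
        profiles = rng.lognormal(mean=np.log(50.0), sigma=1.0,
                                 size=(len(gene_ids), k))
        block = max(1, len(gene_ids) // k)
        for j in range(k):
            profiles[j * block:(j + 1) * block, j] *= 20.0
        mat = pd.DataFrame(profiles, index=gene_ids, columns=types)
        if np.linalg.matrix_rank(mat.values) == k:
            return SignatureMatrix(profiles=mat, coarse_map=coarse)
    raise RuntimeError("could not draw a full-rank signature matrix")


def _cell_dirichlet_alpha(types: list[str], coarse: Mapping[str, str],
                          concentration: float = 60.0) -> np.ndarray:
    counts: dict[str, int] = {}
    for t in types:
        counts[coarse[t]] = counts.get(coarse[t], 0) + 1
    alpha = np.array([
        _COARSE_TARGET.get(coarse[t], 0.05) / counts[coarse[t]] for t in types
    ])
    return alpha / alpha.sum() * concentration


def _metadata(rng: np.random.Generator, config: CohortConfig) -> pd.DataFrame:
    n = config.n_samples
    sep = _markov_sep(rng, n, config.sep_prevalence, config.sep_correlation)
    age = rng.normal(52.5, 8.0, n) + 1.7 * sep[:, 0]
    gender = np.where(rng.random(n) < 0.72, "woman", "man")
    centre = rng.choice(["North", "Central", "South"], size=n, p=[0.44, 0.47, 0.09])
    phase = np.where(rng.random(n) < 0.74, 1, 2)
    bc_case = (rng.random(n) < 0.16).astype(int)
    nhl_case = ((rng.random(n) < 0.33) & (bc_case == 0)).astype(int)
    bmi = rng.normal(25.3, 3.4, n) + 0.7 * sep[:, 0]
    p_never = 0.44 + 0.13 * sep[:, 1]
    p_former = 0.30 - 0.08 * sep[:, 1]
    smoking = np.empty(n, dtype=object)
    u = rng.random(n)
    smoking[u < p_never] = "never"
    smoking[(u >= p_never) & (u < p_never + p_former)] = "former"
    smoking[u >= p_never + p_former] = "current"
    alcohol = rng.gamma(shape=0.8, scale=15.0, size=n)

    def batches(prefix: str, size: int) -> np.ndarray:
        n_b = int(np.ceil(n / size))
        labels = np.repeat([f"{prefix}{b + 1:02d}" for b in range(n_b)], size)[:n]
        return labels[rng.permutation(n)]

    meta = pd.DataFrame({
        "sep_early": sep[:, 0], "sep_young": sep[:, 1], "sep_adult": sep[:, 2],
        "age": age, "gender": gender, "centre": centre, "phase": phase,
        "bc_case": bc_case, "nhl_case": nhl_case, "bmi": bmi,
        "smoking": smoking, "alcohol": alcohol,
        "batch_isolation": batches("iso", 10),
        "batch_hybridization": batches("hyb", 8),
        "batch_labeling": batches("lab", 12),
    }, index=pd.Index([f"S{i + 1:04d}" for i in range(n)], name="sample_id"))
    # questionnaire missingness on the SEP items
    for col, rate in zip(("sep_early", "sep_young", "sep_adult"), config.sep_missing):
        if rate > 0:
            miss = rng.random(n) < rate
            meta.loc[miss, col] = np.nan
    return meta


def generate_cohort(config: CohortConfig | None = None) -> Cohort:
    """Generate a full synthetic cohort.

    The probe-level log2 expression of probe p (gene g) in sample i is

        mu_g + offset_p + delta * sep_early_i * [g inflammatory]
             + sum_c beta_c * covariate_ci
             + u_iso(g, i) + u_hyb(g, i) + u_lab(g, i)
             + s_cell * (S_std w_i)_g  (signature genes only)
             + e_pi

    with gene-specific batch random intercepts and Gaussian noise.  The probe
    planted as "most variable" carries the full noise SD; sibling probes are
    damped, so collapsing by maximal variance recovers the planted probe and
    the collapsed matrix has homogeneous noise.
    """
    if config is None:
        config = CohortConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)

    meta = _metadata(rng, config)
    gene_list = generate_gene_list(config, rng)
    genes = sorted(gene_list.universe)
    g_index = {g: j for j, g in enumerate(genes)}
    n, G = config.n_samples, config.n_genes

    # latent cell composition and its expression contribution
    sig_gene_count = config.signature_genes_per_type * config.n_cell_types
    sig_genes = list(rng.choice(genes, size=min(sig_gene_count, G), replace=False))
    sig_genes.sort()
    signature = generate_signature(config, rng, gene_ids=sig_genes)
    types = list(signature.profiles.columns)
    alpha = _cell_dirichlet_alpha(types, signature.coarse_map)
    w = rng.dirichlet(alpha, size=n)                      # samples x types
    true_props = pd.DataFrame(w, index=meta.index, columns=types)
    coarse = true_props.T.groupby(
        pd.Series(signature.coarse_map)).sum().T
    for cls in ("Lymphocytes", "Neutrophils", "Monocytes"):
        meta[f"true_prop_{cls.lower()}"] = coarse.get(cls, 0.0)

    # gene-level systematic component (genes x samples)
    mu = rng.normal(7.0, 1.5, G)
    sep_early = np.nan_to_num(meta["sep_early"].to_numpy(float), nan=0.0)
    inflam = np.zeros(G)
    for g in gene_list.genes:
        inflam[g_index[g]] = 1.0
    signal = np.tile(mu[:, None], (1, n))
    signal += config.effect_delta * np.outer(inflam, sep_early)

    cov_values = {
        "age": meta["age"].to_numpy(float),
        "bmi": meta["bmi"].to_numpy(float),
        "alcohol": meta["alcohol"].to_numpy(float),
        "smoking_current": (meta["smoking"] == "current").to_numpy(float),
        "smoking_former": (meta["smoking"] == "former").to_numpy(float),
        "gender_man": (meta["gender"] == "man").to_numpy(float),
    }
    for name, beta in config.confounder_effects.items():
        if name not in cov_values:
            raise ValueError(f"unknown confounder '{name}' in confounder_effects")
        v = cov_values[name]
        signal += beta * (v - v.mean())[None, :]

    for factor, sd in zip(
        ("batch_isolation", "batch_hybridization", "batch_labeling"), config.batch_sd
    ):
        if sd <= 0:
            continue
        codes, _ = pd.factorize(meta[factor])
        u = rng.normal(0.0, sd, size=(G, codes.max() + 1))
        signal += u[:, codes]

    if config.cell_effect_sd > 0:
        prof = signature.profiles.to_numpy(float)
        prof_std = (prof - prof.mean(axis=1, keepdims=True))
        prof_std /= np.maximum(prof.std(axis=1, keepdims=True), 1e-12)
        contrib = prof_std @ w.T                          # sig genes x samples
        contrib = (contrib - contrib.mean(axis=1, keepdims=True))
        contrib /= np.maximum(contrib.std(axis=1, keepdims=True), 1e-12)
        rows = [g_index[g] for g in sig_genes]
        signal[rows, :] += config.cell_effect_sd * contrib

    # probe layer
    extra = (rng.poisson(config.probes_per_gene_mean - 1.0, G)
             if config.probes_per_gene_mean > 1 else np.zeros(G, dtype=int))
    n_probes_per_gene = 1 + extra
    probe_rows = []
    probe_ids: list[str] = []
    probe_gene: list[str] = []
    planted: dict[str, str] = {}
    noise_damp = 0.55   # sibling probes get damped noise -> planted probe wins
    for j, g in enumerate(genes):
        kp = n_probes_per_gene[j]
        offsets = rng.normal(0.0, 0.3, kp)
        winner = int(rng.integers(kp))
        for p in range(kp):
            pid = f"{g}_p{p + 1}"
            sd = config.noise_sd if p == winner else config.noise_sd * noise_damp
            row = signal[j] + offsets[p] + rng.normal(0.0, sd, n)
            probe_rows.append(row)
            probe_ids.append(pid)
            probe_gene.append(g)
            if p == winner:
                planted[g] = pid
    expr = pd.DataFrame(np.asarray(probe_rows), index=pd.Index(probe_ids, name="probe_id"),
                        columns=meta.index)
    probe_to_gene = pd.Series(probe_gene, index=expr.index, name="gene_id")
    return Cohort(
        expression=expr, metadata=meta, gene_list=gene_list, signature=signature,
        probe_to_gene=probe_to_gene,
        planted_probe=pd.Series(planted, name="probe_id").sort_index(),
        true_cell_props=true_props, config=config,
    )


# ---------------------------------------------------------------------------
# generator truth for the composite quartile score


def expected_quartile_shift(delta: float, sigma: float, prevalence: float,
                            n_genes: int, tail: float = 0.25) -> float:
    """Expected composite-score contrast (low minus high SEP group).

    Closed-form expectation under the generative model with no batch,
    confounder or cell contribution: per gene the expression is a two-group
    Gaussian mixture N(0, sigma^2) / N(delta, sigma^2) with mixing weight
    ``prevalence`` on the shifted group; the score threshold is the mixture's
    upper ``tail`` quantile, and the per-gene contrast is the difference in
    exceedance probabilities, summed over ``n_genes``.
    """
    if delta == 0:
        return 0.0

    def mixture_tail(t: float) -> float:
        return ((1 - prevalence) * stats.norm.sf(t, 0.0, sigma)
                + prevalence * stats.norm.sf(t, delta, sigma) - tail)

    lo = min(0.0, delta) - 10 * sigma
    hi = max(0.0, delta) + 10 * sigma
    t = optimize.brentq(mixture_tail, lo, hi)
    per_gene = stats.norm.sf(t, delta, sigma) - stats.norm.sf(t, 0.0, sigma)
    return n_genes * per_gene


def calibrate_effect_delta(target_shift: float, sigma: float, prevalence: float,
                           n_genes: int) -> float:
    """Invert :func:`expected_quartile_shift` for the per-gene log2 shift."""
    if target_shift == 0:
        return 0.0
    f = lambda d: expected_quartile_shift(d, sigma, prevalence, n_genes) - target_shift
    return optimize.brentq(f, 1e-9, 10 * sigma)


# ---------------------------------------------------------------------------
# writers


def write_cohort(cohort: Cohort, outdir) -> dict[str, str]:
    """Write the cohort as plain-text tables plus a YAML manifest."""
    import pathlib

    import yaml

    out = pathlib.Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "expression": out / "expression.tsv",
        "metadata": out / "metadata.csv",
        "gene_list": out / "gene_list.tsv",
        "probe_to_gene": out / "probe_to_gene.tsv",
        "signature": out / "signature.tsv",
        "coarse_map": out / "coarse_map.tsv",
        "manifest": out / "manifest.yaml",
    }
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.metadata.to_csv(paths["metadata"])
    gl = pd.DataFrame({
        "gene_id": cohort.gene_list.genes,
        "subpathway": [cohort.gene_list.subpathway.get(g, "")
                       for g in cohort.gene_list.genes],
    })
    gl.to_csv(paths["gene_list"], sep="\t", index=False)
    cohort.probe_to_gene.rename_axis("probe_id").to_csv(paths["probe_to_gene"], sep="\t")
    cohort.signature.profiles.rename_axis("gene_id").to_csv(paths["signature"], sep="\t")
    pd.Series(cohort.signature.coarse_map, name="coarse").rename_axis("cell_type") \
        .to_csv(paths["coarse_map"], sep="\t")
    manifest = {"config": dataclasses.asdict(cohort.config)}
    manifest["config"]["confounder_effects"] = dict(cohort.config.confounder_effects)
    with open(paths["manifest"], "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
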