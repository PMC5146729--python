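"""End-to-end orchestration: synthetic or file-based full runs, and the
replication path for external GEO-format data.

Stage order of a full run: probe collapsing -> panel intersection ->
[quantile normalization for external probe-level data] -> mixed-model
de-noising -> composite and sub-pathway scores -> life-course association
ladder -> random-gene-set specificity null -> cell-type deconvolution ->
fully adjusted model.  Every run writes its tables as CSV plus a manifest
(YAML) from which it can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import pathlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import GeneList, collapse_probes, read_gene_list, select_inflammatory
from .association import (AssociationResult, life_course_ladder,
                          score_association, score_correlations)
from .cohort import Cohort, CohortConfig, generate_cohort
from .deconvolution import SignatureMatrix, estimate_proportions, read_signature
from .design import analysis_set
from .geo import derive_binary_exposure, read_platform_annotation, read_series_matrix
from .preprocess import denoise, quantile_normalize
from .scores import pc1_score, quartile_score, rank_score, subpathway_scores
from .specificity import random_geneset_null

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "RunResult", "run_full", "run_replication",
           "plot_score_by_group"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Either ``cohort`` (a synthetic-cohort configuration) or the four input
    paths must be provided.  Stage toggles allow skipping de-noising (for
    batch-free data) and the specificity null (for quick runs).
    """

    output_dir: str = "inflamscore_run"
    cohort: CohortConfig | None = None
    expression_path: str | None = None          # probe-level TSV
    metadata_path: str | None = None
    gene_list_path: str | None = None
    probe_to_gene_path: str | None = None
    signature_path: str | None = None
    coarse_map_path: str | None = None
    external_probe_level: bool = False          # quantile-normalize first
    run_denoise: bool = True
    denoise_method: str = "reml"
    run_specificity: bool = True
    sep_indicators: tuple[str, ...] = ("sep_early", "sep_young", "sep_adult")
    primary_sep: str = "sep_early"
    models: tuple[str, ...] = ("A", "B", "C", "D", "fully_adjusted")
    rank_aggregate: str = "median"
    n_sets: int = 1000
    set_size: int | None = None                 # default: panel size
    seed: int = 0

    def to_manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.cohort is not None:
            d["cohort"] = dataclasses.asdict(self.cohort)
            d["cohort"]["confounder_effects"] = dict(self.cohort.confounder_effects)
        return d


@dataclass
class RunResult:
    """In-memory handles plus the paths of everything a run wrote."""

    scores: pd.DataFrame
    associations: pd.DataFrame
    specificity_summary: dict | None
    proportions: pd.DataFrame | None
    coverage: float
    paths: dict[str, str] = field(default_factory=dict)


def _load_inputs(config: PipelineConfig) -> tuple[pd.DataFrame, pd.DataFrame,
                                                  GeneList, pd.Series,
                                                  SignatureMatrix | None]:
    if config.cohort is not None:
        cohort: Cohort = generate_cohort(config.cohort)
        return (cohort.expression, cohort.metadata, cohort.gene_list,
                cohort.probe_to_gene, cohort.signature)
    missing = [n for n in ("expression_path", "metadata_path", "gene_list_path",
                           "probe_to_gene_path") if getattr(config, n) is None]
    if missing:
        raise ValueError(f"pipeline config lacks inputs: {missing}")
    expr = pd.read_csv(config.expression_path, sep="\t", index_col=0)
    meta = pd.read_csv(config.metadata_path, index_col=0)
    p2g = pd.read_csv(config.probe_to_gene_path, sep="\t", index_col=0).iloc[:, 0]
    gene_list = read_gene_list(config.gene_list_path)
    sig = None
    if config.signature_path and config.coarse_map_path:
        sig = read_signature(config.signature_path, config.coarse_map_path)
    return expr, meta, gene_list, p2g, sig


def run_full(config: PipelineConfig) -> RunResult:
    """Execute the full analysis and write all outputs.

    Any stage failure raises with the stage name; outputs written before the
    failure are retained for inspection.
    """
    out = pathlib.Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    def _write(name: str, df: pd.DataFrame) -> None:
        p = out / f"{name}.csv"
        df.to_csv(p, float_format="%.10g")
        paths[name] = str(p)

    def _stage(name):
        logger.info("stage: %s", name)

    try:
        _stage("load")
        expr_probe, meta, gene_list, p2g, signature = _load_inputs(config)

        _stage("collapse")
        expr = collapse_probes(expr_probe, p2g)

        if config.external_probe_level:
            _stage("quantile_normalize")
            expr = quantile_normalize(expr)

        _stage("select_inflammatory")
        panel, coverage = select_inflammatory(expr, gene_list)

        if config.run_denoise:
            _stage("denoise")
            den = denoise(expr, meta, sep=config.primary_sep,
                          method=config.denoise_method)
            expr_dn = den.values
            _write("denoise_fit_log", den.fit_log)
        else:
            expr_dn = expr
        panel_dn = expr_dn.loc[panel.index]

        _stage("scores")
        scores = quartile_score(panel_dn).to_frame()
        pc1, pc1_var = pc1_score(panel_dn)
        scores["pc1_score"] = pc1
        for sep in config.sep_indicators:
            if sep in meta.columns and meta[sep].nunique(dropna=True) == 2:
                scores[f"rank_score_{sep}"] = rank_score(
                    panel_dn, meta[sep], aggregate=config.rank_aggregate)
        sub = subpathway_scores(expr_dn, gene_list)
        scores = pd.concat([scores, sub], axis=1)
        _write("scores", scores)
        _write("score_correlations", score_correlations(scores))

        _stage("associations")
        assoc_rows = []
        for sep in config.sep_indicators:
            if sep not in meta.columns:
                continue
            for outcome in ("quartile_score", "pc1_score", f"rank_score_{sep}"):
                if outcome not in scores.columns:
                    continue
                ladder = life_course_ladder(
                    scores[outcome].rename(outcome), meta, sep=sep,
                    models=tuple(m for m in config.models
                                 if m != "fully_adjusted"))
                assoc_rows.append(ladder.reset_index())
        associations = pd.concat(assoc_rows, ignore_index=True) \
            if assoc_rows else pd.DataFrame()

        _stage("specificity")
        spec_summary = None
        if config.run_specificity:
            nd = random_geneset_null(
                expr_dn, meta, sep=config.primary_sep,
                set_size=config.set_size or panel.shape[0],
                n_sets=config.n_sets, seed=config.seed,
                observed_genes=list(panel.index))
            spec_summary = nd.summary()
            _write("specificity_null", pd.DataFrame(
                {"set_index": np.arange(nd.n_sets),
                 "beta": nd.null_beta, "pvalue": nd.null_p}).set_index("set_index"))

        _stage("deconvolution")
        proportions = None
        if signature is not None:
            props = estimate_proportions(expr, signature)
            proportions = props.coarse
            meta = meta.copy()
            meta["prop_neutrophils"] = props.coarse["Neutrophils"]
            meta["prop_monocytes"] = props.coarse["Monocytes"]
            _write("cell_proportions", pd.concat(
                [props.fine, props.coarse.add_prefix("coarse_")], axis=1))

        _stage("fully_adjusted")
        if signature is not None and "fully_adjusted" in config.models:
            fa_rows = []
            for sep in config.sep_indicators:
                if sep not in meta.columns:
                    continue
                res = score_association(scores["quartile_score"], meta,
                                        sep=sep, model="fully_adjusted")
                fa_rows.append(res.to_dict())
            if fa_rows:
                fa = pd.DataFrame(fa_rows)
                fa["model"] = "fully_adjusted"
                associations = pd.concat([associations, fa], ignore_index=True)
        _write("associations", associations)

        _stage("manifest")
        manifest = {
            "config": config.to_manifest(),
            "version": __version__,
            "coverage": coverage,
            "pc1_variance_explained": pc1_var,
            "n_analysis": int(len(analysis_set(meta))),
        }
        if spec_summary:
            manifest["specificity"] = {k: (v if not isinstance(v, np.generic)
                                           else v.item())
                                       for k, v in spec_summary.items()}
        manifest_text = yaml.safe_dump(manifest, sort_keys=True)
        manifest["config_hash"] = hashlib.sha256(manifest_text.encode()).hexdigest()
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
        paths["manifest"] = str(out / "manifest.yaml")
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage "
                           f"'{getattr(exc, 'stage', 'see traceback')}': {exc}") from exc

    return RunResult(scores=scores, associations=associations,
                     specificity_summary=spec_summary, proportions=proportions,
                     coverage=coverage, paths=paths)


def run_replication(series_matrix_path, annotation_path,
                    gene_list: GeneList,
                    sep_key: str,
                    sep_low_values: list[str],
                    sep_high_values: list[str],
                    signature: SignatureMatrix | None = None,
                    gene_col: str = "Symbol",
                    rank_aggregate: str = "median") -> dict:
    """Replication on an external GEO-format dataset.

    Quantile normalization on probe intensities -> probe collapsing ->
    inflammatory-panel intersection -> the three composite scores ->
    unadjusted linear regression on the derived early-life SEP indicator,
    plus (when a signature is supplied) a second fit adjusted for estimated
    neutrophil and monocyte proportions.
    """
    sm = read_series_matrix(series_matrix_path)
    p2g = read_platform_annotation(annotation_path, gene_col=gene_col)
    sep = derive_binary_exposure(sm, sep_key, sep_low_values, sep_high_values)

    expr = quantile_normalize(sm.expression)
    expr = collapse_probes(expr, p2g)
    panel, coverage = select_inflammatory(expr, gene_list)

    meta = pd.DataFrame({"sep_early": sep})
    scores = quartile_score(panel).to_frame()
    pc1, pc1_var = pc1_score(panel)
    scores["pc1_score"] = pc1
    scores["rank_score"] = rank_score(panel, sep, aggregate=rank_aggregate)

    results: dict[str, AssociationResult] = {}
    for outcome in ("quartile_score", "pc1_score", "rank_score"):
        results[outcome] = score_association(
            scores[outcome].rename(outcome), meta, sep="sep_early",
            model="unadjusted", samples=meta.index)
    adjusted: dict[str, AssociationResult] = {}
    if signature is not None:
        props = estimate_proportions(expr, signature)
        meta["prop_neutrophils"] = props.coarse["Neutrophils"]
        meta["prop_monocytes"] = props.coarse["Monocytes"]
        for outcome in ("quartile_score", "pc1_score", "rank_score"):
            X_terms = ("prop_neutrophils", "prop_monocytes")
            from .association import ols_exposure_test
            from .design import build_design
            X = build_design(meta, X_terms, sep="sep_early")
            beta, se, p = ols_exposure_test(
                X.to_numpy(float), scores[outcome].to_numpy(float))
            adjusted[outcome] = AssociationResult(
                outcome=outcome, exposure="sep_early", model="cell_adjusted",
                beta=beta, se=se, pvalue=p, n=len(meta), adjustment=X_terms)
    return {"coverage": coverage, "n_panel_genes": panel.shape[0],
            "pc1_variance_explained": pc1_var, "scores": scores,
            "unadjusted": results, "cell_adjusted": adjusted}


def plot_score_by_group(score: pd.Series, group: pd.Series, ax=None,
                        labels: tuple[str, str] = ("high SEP", "low SEP")):
    """Boxplot of a composite score by a binary SEP indicator."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    g = group.loc[score.index]
    data = [score[g == 0].dropna(), score[g == 1].dropna()]
    ax.boxplot(data, tick_labels=list(labels))
    ax.set_ylabel(score.name or "score")
    return ax
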