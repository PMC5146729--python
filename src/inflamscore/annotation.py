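"""Probe-to-gene collapsing and inflammatory-panel intersection."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["GeneList", "collapse_probes", "select_inflammatory", "read_gene_list"]


@dataclass
class GeneList:
    """A curated gene panel with optional functional sub-pathway labels.

    ``genes`` is the full panel (it may exceed what a platform measures);
    ``subpathway`` maps a subset of the panel to functional labels;
    ``universe`` is the set of all annotated genes on the platform.
    """

    genes: list[str]
    subpathway: dict[str, str] = field(default_factory=dict)
    universe: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = set(self.subpathway) - set(self.genes)
        if unknown:
            raise ValueError(
                f"sub-pathway labels for genes outside the panel: {sorted(unknown)[:5]}"
            )

    @property
    def subpathway_labels(self) -> list[str]:
        return sorted(set(self.subpathway.values()))

    def genes_in_subpathway(self, label: str) -> list[str]:
        return sorted(g for g, lab in self.subpathway.items() if lab == label)


def read_gene_list(path, universe: set[str] | None = None) -> GeneList:
    """Read a gene-list TSV with columns ``gene_id`` and ``subpathway``."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    genes = df["gene_id"].tolist()
    sub = {g: s for g, s in zip(df["gene_id"], df.get("subpathway", "")) if s}
    return GeneList(genes=genes, subpathway=sub, universe=universe or set())


def collapse_probes(expr: pd.DataFrame,
                    probe_to_gene: Mapping[str, str] | pd.Series) -> pd.DataFrame:
    """Collapse a probe-level matrix to gene level by the most variable probe.

    For genes measured by several probes the probe with the largest unbiased
    sample variance across samples is retained; variance ties break by
    lexicographic probe id (logged).  Probes without a gene annotation are
    dropped.  Rows of the result are sorted by gene id.  Gene-level input
    (identity mapping) passes through unchanged, so the operation is
    idempotent.
    """
    mapping = pd.Series(dict(probe_to_gene)) if not isinstance(probe_to_gene, pd.Series) \
        else probe_to_gene
    mapping = mapping.dropna()
    mapping = mapping[mapping.astype(str) != ""]
    if mapping.empty:
        raise ValueError("probe-to-gene mapping is empty")
    keep = expr.index.intersection(mapping.index)
    if keep.empty:
        raise ValueError("no probe in the expression matrix has a gene annotation")
    sub = expr.loc[keep]
    variances = sub.var(axis=1, ddof=1)
    choice = pd.DataFrame({
        "gene": mapping.loc[keep].to_numpy(),
        "var": variances.to_numpy(),
        "probe": keep.to_numpy(),
    })
    # sort so the winner (max variance, lexicographically first probe on ties)
    # is the first row per gene
    choice = choice.sort_values(["gene", "var", "probe"],
                                ascending=[True, False, True], kind="mergesort")
    ties = choice.duplicated(subset=["gene", "var"], keep=False)
    if ties.any():
        tied_genes = choice.loc[ties, "gene"].unique()
        logger.info("variance ties broken by probe id for %d gene(s): %s",
                    len(tied_genes), ", ".join(map(str, tied_genes[:5])))
    winners = choice.drop_duplicates(subset="gene", keep="first")
    out = sub.loc[winners["probe"]]
    out.index = pd.Index(winners["gene"].to_numpy(), name="gene_id")
    return out.sort_index()


def select_inflammatory(expr: pd.DataFrame,
                        gene_list: GeneList) -> tuple[pd.DataFrame, float]:
    """Restrict a gene-level matrix to the panel; report panel coverage.

    Coverage is the fraction of the panel present in the measured matrix
    (e.g. 845 of 1,027 genes -> 0.823).
    """
    panel = pd.Index(sorted(set(gene_list.genes)))
    present = panel.intersection(expr.index)
    if present.empty:
        raise ValueError("no panel gene is present in the expression matrix")
    coverage = len(present) / len(panel)
    return expr.loc[present].sort_index(), coverage
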