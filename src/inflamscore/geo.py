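"""Readers and writers for GEO-style plain-text formats.

Supports the two files the replication path needs: a series-matrix file
(header lines starting with ``!``, then a probe-by-sample table between
``!series_matrix_table_begin`` and ``!series_matrix_table_end``) and a SOFT
platform-annotation table (probe-to-gene mapping after
``!platform_table_begin``).  Both quoted and unquoted dialects are accepted.
Nothing here touches the network; files must be supplied locally.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["SeriesMatrix", "read_series_matrix", "read_platform_annotation",
           "derive_binary_exposure", "write_series_matrix"]


def _unquote(s: str) -> str:
    s = s.strip()
    if len(s) >= 2 and s[0] == '"' and s[-1] == '"':
        return s[1:-1]
    return s


@dataclass
class SeriesMatrix:
    """Parsed series-matrix content."""

    expression: pd.DataFrame                   # probes x GSM accessions
    sample_characteristics: pd.DataFrame       # samples x characteristic keys
    sample_titles: pd.Series = field(default_factory=pd.Series)
    series_metadata: dict = field(default_factory=dict)


def read_series_matrix(path) -> SeriesMatrix:
    header: dict[str, list[list[str]]] = {}
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if in_table:
                table_lines.append(line)
            elif line.startswith("!"):
                key, *fields_ = line.split("\t")
                header.setdefault(key.lstrip("!"), []).append(
                    [_unquote(f) for f in fields_])
    if not table_lines:
        raise ValueError(f"{path}: no series_matrix table block found")
    expr = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t")
    expr.columns = [_unquote(str(c)) for c in expr.columns]
    expr = expr.set_index(expr.columns[0])
    expr.index = [_unquote(str(i)) for i in expr.index]
    expr.index.name = "probe_id"
    expr = expr.astype(float)

    accessions = header.get("Sample_geo_accession", [[]])[0]
    if not accessions:
        accessions = list(expr.columns)
    char_rows = header.get("Sample_characteristics_ch1", [])
    parsed: dict[str, list[str]] = {}
    for r_i, row in enumerate(char_rows):
        for j, cell in enumerate(row):
            if ":" in cell:
                key, val = cell.split(":", 1)
                key, val = key.strip(), val.strip()
            else:
                key, val = f"characteristic_{r_i}", cell.strip()
            parsed.setdefault(key, [""] * len(accessions))
            if j < len(accessions):
                parsed[key][j] = val
    chars = pd.DataFrame(parsed, index=pd.Index(accessions, name="sample_id"))
    titles = pd.Series(header.get("Sample_title", [[]])[0] or [""] * len(accessions),
                       index=accessions, name="title")
    series_meta = {k: v[0][0] if v and v[0] else "" for k, v in header.items()
                   if k.startswith("Series_")}
    return SeriesMatrix(expression=expr, sample_characteristics=chars,
                        sample_titles=titles, series_metadata=series_meta)


def read_platform_annotation(path, probe_col: str = "ID",
                             gene_col: str = "Symbol") -> pd.Series:
    """Probe-to-gene mapping from a SOFT platform annotation table."""
    table_lines: list[str] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!platform_table_begin"):
                in_table = True
                continue
            if line.startswith("!platform_table_end"):
                break
            if in_table:
                table_lines.append(line)
            elif not (line.startswith(("^", "!", "#"))) and "\t" in line and not in_table:
                # tolerate bare tables without SOFT markers
                table_lines.append(line)
    if not table_lines:
        raise ValueError(f"{path}: no platform annotation table found")
    tab = pd.read_csv(io.StringIO("\n".join(table_lines)), sep="\t", dtype=str)
    if probe_col not in tab.columns or gene_col not in tab.columns:
        raise ValueError(
            f"{path}: expected columns '{probe_col}' and '{gene_col}', "
            f"found {list(tab.columns)[:10]}")
    mapping = tab.set_index(probe_col)[gene_col]
    mapping = mapping[mapping.notna() & (mapping.str.strip() != "")]
    return mapping.rename("gene_id")


def derive_binary_exposure(sm: SeriesMatrix, key: str,
                           low_values: set[str] | list[str],
                           high_values: set[str] | list[str]) -> pd.Series:
    """Binary exposure (1 = low SEP) from a sample-characteristics field.

    Raises with the list of unparsed fields when any sample's value matches
    neither class.
    """
    if key not in sm.sample_characteristics.columns:
        raise ValueError(
            f"characteristic '{key}' not found; available: "
            f"{list(sm.sample_characteristics.columns)}")
    vals = sm.sample_characteristics[key].str.strip().str.lower()
    low = {v.lower() for v in low_values}
    high = {v.lower() for v in high_values}
    out = pd.Series(np.nan, index=vals.index, name="sep_early")
    out[vals.isin(low)] = 1.0
    out[vals.isin(high)] = 0.0
    if out.isna().any():
        bad = sorted(vals[out.isna()].unique())
        raise ValueError(f"unmatched exposure labels: {bad}")
    return out


def write_series_matrix(path, expression: pd.DataFrame,
                        characteristics: pd.DataFrame,
                        series_title: str = "synthetic series") -> None:
    """Write a minimal series-matrix file (used for fixtures and examples)."""
    acc = list(expression.columns)
    with open(path, "w") as fh:
        fh.write(f'!Series_title\t"{series_title}"\n')
        fh.write("!Sample_geo_accession\t" +
                 "\t".join(f'"{a}"' for a in acc) + "\n")
        fh.write("!Sample_title\t" + "\t".join(f'"{a}"' for a in acc) + "\n")
        for col in characteristics.columns:
            cells = "\t".join(f'"{col}: {characteristics.loc[a, col]}"' for a in acc)
            fh.write(f"!Sample_characteristics_ch1\t{cells}\n")
        fh.write("!series_matrix_table_begin\n")
        fh.write('"ID_REF"\t' + "\t".join(f'"{a}"' for a in acc) + "\n")
        for pid, row in expression.iterrows():
            fh.write(f'"{pid}"\t' + "\t".join(f"{v:.6g}" for v in row) + "\n")
        fh.write("!series_matrix_table_end\n")
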