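"""Readers and writers for the pipeline's plain-text formats.

Expression and design tables are TSV; gene sets are GMT (see
``enrichment``); dendrograms are Newick; the run report is JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_design",
    "write_design",
    "write_tsv",
    "write_report",
]


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV: gene IDs in the first column, sample IDs in the header."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    dupes = df.index[df.index.duplicated()]
    if len(dupes):
        raise ValueError(f"duplicate gene ID {dupes[0]!r} in {path}")
    for col in df.columns:
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric cell in {path}: gene {bad.index[0]!r}, sample {col!r}"
            )
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        sample = df.columns[df.loc[gene].isna()][0]
        raise ValueError(f"missing value in {path}: gene {gene!r}, sample {sample!r}")
    return df


def write_expression(expr: pd.DataFrame, path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.10g")


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "treatment": str})
    required = {"sample_id", "treatment"}
    missing = required - set(design.columns)
    if missing:
        raise ValueError(f"design table {path} lacks columns: {sorted(missing)}")
    return design


def write_design(design: pd.DataFrame, path) -> None:
    design.to_csv(path, sep="\t", index=False)


def write_tsv(df: pd.DataFrame, path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def write_report(report: dict, path) -> None:
    """JSON run report with a schema tag and stable key order."""
    payload = {"schema": "follinet-report-1", **report}
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True, default=_json_default))


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, set):
        return sorted(obj)
    raise TypeError(f"cannot serialize {type(obj)}")
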