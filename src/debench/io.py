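"""Plain-text (TSV/JSON) readers and writers for the pipeline's formats.

Formats:

* counts TSV — first column ``gene_id``, remaining columns samples,
  integer cells;
* design TSV — columns ``sample`` and ``group``;
* panel TSV — columns ``gene_id``, ``mu``, ``phi``;
* truth TSV — columns ``gene_id``, ``d``, ``fc``;
* results TSV — columns ``gene_id``, ``p``, ``p_adj``, ``fc``,
  ``direction`` (empty for directionless methods).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .methods import MethodResult
from .panel import NBGeneParams

__all__ = [
    "read_counts", "write_counts",
    "read_design", "write_design",
    "read_panel", "write_panel",
    "read_truth", "write_truth",
    "read_result", "write_result",
]


def read_counts(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    mat = df.to_numpy()
    if np.any(mat < 0):
        raise ValueError(f"{path}: counts must be non-negative")
    if not np.allclose(mat, np.round(mat)):
        raise ValueError(f"{path}: counts must be integers")
    return df.astype(np.int64)


def write_counts(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_design(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "group"} <= set(df.columns):
        raise ValueError(f"{path}: design needs 'sample' and 'group' columns")
    return df


def write_design(samples, groups, path) -> None:
    pd.DataFrame({"sample": samples, "group": groups}).to_csv(
        path, sep="\t", index=False
    )


def read_panel(path) -> NBGeneParams:
    return NBGeneParams.from_frame(pd.read_csv(path, sep="\t"))


def write_panel(panel: NBGeneParams, path) -> None:
    panel.to_frame().to_csv(path, sep="\t", index=False)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_truth(truth_frame: pd.DataFrame, path) -> None:
    truth_frame.to_csv(path, sep="\t", index=False)


def write_result(result: MethodResult, path) -> None:
    result.to_frame().to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_result(path, method: str | None = None) -> MethodResult:
    df = pd.read_csv(path, sep="\t")
    if method is None:
        method = Path(path).stem
    direction = None
    if df["direction"].notna().any():
        direction = df["direction"].to_numpy(dtype=float).astype(np.int8)
    return MethodResult(
        method=method,
        gene_id=df["gene_id"].to_numpy(dtype=object),
        p=df["p"].to_numpy(dtype=float),
        p_adjusted=df["p_adj"].to_numpy(dtype=float),
        fc_estimate=df["fc"].to_numpy(dtype=float),
        norm_factors=np.ones(1),
        direction=direction,
    )
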