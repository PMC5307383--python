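"""Readers and writers for count matrices, sample tables, qPCR plates and results.

All on-disk formats are plain text: TSV for the count matrix (first column
``mir_id``, header = sample ids), CSV for sample metadata and qPCR plates,
TSV/JSON for result tables plus a JSON manifest.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CountMatrix, FormatError, SampleTable

logger = logging.getLogger(__name__)

#: tolerance for the non-strict integer check (export artifacts like "12.0")
_INT_TOL = 1e-9


def read_count_matrix(
    path, sep: str = "\t", feature_col: str | int = 0, strict: bool = True
) -> CountMatrix:
    """Read a miR-by-sample count matrix.

    Parameters
    ----------
    sep, feature_col
        File dialect: field separator and the name or position of the
        feature-id column.
    strict
        If True, any non-integer entry is an error.  If False, floats within
        1e-9 of an integer are rounded (tolerates spreadsheet exports); the
        Poisson likelihood requires integer support either way.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, not a count matrix") from None
    if df.shape[1] < 2:
        raise FormatError(f"{path}: need a feature column plus >=1 sample column")
    if isinstance(feature_col, int):
        feature_col = df.columns[feature_col]
    if feature_col not in df.columns:
        raise FormatError(f"{path}: no feature column {feature_col!r}")
    df = df.set_index(feature_col)
    df.index = df.index.astype(str)
    df.index.name = "mir_id"

    if df.isna().any().any():
        r, c = next(zip(*np.where(df.isna().to_numpy())))
        raise FormatError(
            f"{path}: missing value at row {df.index[r]!r}, column {df.columns[c]!r}"
        )
    vals = df.to_numpy()
    if not np.issubdtype(vals.dtype, np.number):
        bad = df.columns[[not np.issubdtype(t, np.number) for t in df.dtypes]]
        raise FormatError(f"{path}: non-numeric sample columns: {list(bad)}")
    if not np.issubdtype(vals.dtype, np.integer):
        if strict:
            raise FormatError(f"{path}: non-integer counts (use strict=False to round)")
        rounded = np.rint(vals)
        if np.abs(vals - rounded).max() > _INT_TOL:
            raise FormatError(f"{path}: entries further than {_INT_TOL} from an integer")
        vals = rounded
        df = pd.DataFrame(vals, index=df.index, columns=df.columns)
    df = df.astype(np.int64)
    cm = CountMatrix(df)
    logger.info("%s: parsed %d features x %d samples", path, *cm.shape)
    return cm


def write_count_matrix(cm: CountMatrix, path) -> None:
    df = cm.counts.copy()
    df.index.name = "mir_id"
    df.to_csv(path, sep="\t")


def read_sample_table(path) -> SampleTable:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: empty file, not a sample table") from None
    if "pair_id" in df.columns:
        # blank cells mean singleton; keep ids as strings otherwise
        df["pair_id"] = df["pair_id"].astype(object).where(df["pair_id"].notna(), None)
    return SampleTable(df)


def write_sample_table(st: SampleTable, path) -> None:
    st.table.to_csv(path, index=False)


def read_qpcr_plate(path) -> pd.DataFrame:
    """Read a qPCR plate CSV: sample_id, target_id, ct, is_spike, is_calibrator."""
    df = pd.read_csv(path)
    required = {"sample_id", "target_id", "ct", "is_spike", "is_calibrator"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: plate missing columns {sorted(missing)}")
    df["is_spike"] = df["is_spike"].astype(bool)
    df["is_calibrator"] = df["is_calibrator"].astype(bool)
    if (df["ct"] <= 0).any():
        raise FormatError(f"{path}: Ct values must be positive")
    return df


def write_qpcr_plate(plate: pd.DataFrame, path) -> None:
    plate.to_csv(path, index=False)


def write_results(tables: dict[str, pd.DataFrame], out_dir, formats=("tsv", "json")):
    """Write result tables deterministically and return a manifest.

    Each table is written once per requested format; the manifest lists every
    file with its row count and is itself written as ``manifest.json``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {"files": []}
    for name in sorted(tables):
        df = tables[name]
        if "tsv" in formats:
            p = out_dir / f"{name}.tsv"
            df.to_csv(p, sep="\t", index=False)
            manifest["files"].append({"path": p.name, "rows": int(len(df))})
        if "json" in formats:
            p = out_dir / f"{name}.json"
            p.write_text(df.to_json(orient="records", indent=2) + "\n")
            manifest["files"].append({"path": p.name, "rows": int(len(df))})
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
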