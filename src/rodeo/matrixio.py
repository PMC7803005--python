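"""Delimited-text readers and writers for the three matrix roles.

One canonical layout: a header row of column identifiers, a first column of
row identifiers, tab-delimited by default.  Orientation is always declared
by the caller — ``genes_x_samples`` (bulk E), ``celltypes_x_samples``
(proportions C) or ``genes_x_celltypes`` (signature S) — never sniffed, so a
transposed file fails loudly instead of silently fitting nonsense.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import BulkMatrix, ProportionMatrix, SignatureMatrix
from .errors import ParseError, ValidationError

ORIENTATIONS = {
    "genes_x_samples": BulkMatrix,
    "celltypes_x_samples": ProportionMatrix,
    "genes_x_celltypes": SignatureMatrix,
}


def _parse_table(path: Path, delimiter: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, sep=delimiter, index_col=0, dtype=str, header=0,
                         float_precision="round_trip")
    except Exception as exc:  # pandas raises several parser error types
        raise ParseError(f"{path}: could not parse delimited table: {exc}") from exc
    if df.shape[1] == 0:
        raise ParseError(f"{path}: no data columns found (wrong delimiter?)")
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate row identifiers: {dupes}")
    if pd.Index(df.columns).has_duplicates:
        cols = pd.Index(df.columns)
        dupes = sorted(cols[cols.duplicated()].unique().tolist())
        raise ParseError(f"{path}: duplicate column identifiers: {dupes}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & ~df[col].isna()
        if bad.any() or df[col].isna().any():
            miss = bad | df[col].isna()
            row_pos = int(np.nonzero(miss.to_numpy())[0][0])
            cell = df[col].iloc[row_pos]
            raise ParseError(
                f"{path}: non-numeric cell {cell!r} at row {df.index[row_pos]!r} "
                f"(line {row_pos + 2}), column {col!r}"
            )
        # numpy's strtod is correctly rounded, so written reprs round-trip
        out[col] = df[col].to_numpy(dtype=float)
    if not np.all(np.isfinite(out.to_numpy())):
        raise ParseError(f"{path}: table contains non-finite values")
    return out


def read_matrix(path, orientation: str, delimiter: str = "\t"):
    """Read a delimited matrix file into the typed container for its role.

    The container's invariants are validated on construction (non-negative
    bulk values, simplex proportion columns with renormalization of
    abundance-style columns, finite signatures).
    """
    if orientation not in ORIENTATIONS:
        raise ValidationError(
            f"unknown orientation {orientation!r}; choose from {sorted(ORIENTATIONS)}"
        )
    path = Path(path)
    if not path.is_file():
        raise ParseError(f"{path}: file does not exist")
    df = _parse_table(path, delimiter)
    return ORIENTATIONS[orientation].from_frame(df)


def write_matrix(matrix, path, delimiter: str = "\t") -> Path:
    """Write a typed matrix as delimited text (round-trip safe precision)."""
    if not isinstance(matrix, (BulkMatrix, ProportionMatrix, SignatureMatrix)):
        raise ValidationError(f"cannot write object of type {type(matrix).__name__}")
    path = Path(path)
    df = matrix.to_frame()
    # repr() of a float round-trips exactly; pandas' default str() does too
    # on Python 3, but be explicit.
    with open(path, "w") as fh:
        fh.write(delimiter.join(["id", *df.columns]) + "\n")
        for rid, row in zip(df.index, df.to_numpy()):
            fh.write(delimiter.join([str(rid), *(repr(float(v)) for v in row)]) + "\n")
    return path


def write_metadata(path, entries: dict) -> Path:
    """Write a key=value sidecar (one entry per line, values stringified)."""
    path = Path(path)
    with open(path, "w") as fh:
        for key, value in entries.items():
            if isinstance(value, (set, frozenset)):
                value = ",".join(sorted(map(str, value)))
            elif isinstance(value, (list, tuple)):
                value = ",".join(map(str, value))
            fh.write(f"{key}={value}\n")
    return path


def save_dataset(dataset, out_dir, delimiter: str = "\t") -> Path:
    """Write a synthetic dataset (E, C, truth S, metadata) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_matrix(dataset.E, out / "bulk.tsv", delimiter)
    write_matrix(dataset.C, out / "proportions.tsv", delimiter)
    write_matrix(dataset.truth_S, out / "truth_signature.tsv", delimiter)
    cfg = dataset.config
    meta = {f"config.{k}": v for k, v in vars(cfg).items()}
    meta.update(
        batch_genes=dataset.batch_genes,
        batch_samples=dataset.batch_samples,
        outlier_samples=dataset.outlier_samples,
    )
    write_metadata(out / "metadata.txt", meta)
    return out
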