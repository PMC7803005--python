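"""Typed matrix containers for the deconvolution model E = S @ C.

Orientation is fixed throughout the package: genes are rows of the bulk
matrix E and the signature matrix S; cell types are rows of the proportion
matrix C and columns of S.  Each container validates its own invariants at
construction, so downstream code can assume them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError

#: Tolerance within which a proportion column is accepted as summing to 1.
SIMPLEX_TOL = 1e-6


def _check_ids(ids, what: str) -> list[str]:
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate {what} identifiers: {dupes}")
    return ids


def _as_matrix(values, n_rows: int, n_cols: int, what: str) -> np.ndarray:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if values.shape != (n_rows, n_cols):
        raise ValidationError(
            f"{what} values have shape {values.shape}, expected ({n_rows}, {n_cols})"
        )
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{what} contains non-finite values")
    return values


@dataclass
class BulkMatrix:
    """Bulk expression E: genes x samples, non-negative."""

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        if len(self.gene_ids) < 1:
            raise ValidationError("bulk matrix needs at least one gene")
        if len(self.sample_ids) < 2:
            raise ValidationError("bulk matrix needs at least two samples")
        self.values = _as_matrix(
            self.values, len(self.gene_ids), len(self.sample_ids), "bulk matrix"
        )
        if np.any(self.values < 0):
            g, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"bulk expression must be non-negative; negative value at "
                f"gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BulkMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class ProportionMatrix:
    """Cell-type proportions C: cell types x samples, columns on the simplex.

    Columns whose sum deviates from 1 by more than ``SIMPLEX_TOL`` but are
    non-negative are interpreted as unscaled abundances and renormalized
    with a warning; any negative entry is a hard error.
    """

    values: np.ndarray
    celltype_ids: list[str]
    sample_ids: list[str]

    def __post_init__(self) -> None:
        self.celltype_ids = _check_ids(self.celltype_ids, "cell type")
        self.sample_ids = _check_ids(self.sample_ids, "sample")
        self.values = _as_matrix(
            self.values, len(self.celltype_ids), len(self.sample_ids), "proportions"
        )
        if np.any(self.values < 0):
            t, s = np.argwhere(self.values < 0)[0]
            raise ValidationError(
                f"proportions must be non-negative; negative value for cell type "
                f"{self.celltype_ids[t]!r} in sample {self.sample_ids[s]!r}"
            )
        sums = self.values.sum(axis=0)
        if np.any(sums <= 0):
            s = int(np.argmin(sums))
            raise ValidationError(
                f"proportion column {self.sample_ids[s]!r} sums to {sums[s]}; "
                "every sample needs positive total composition"
            )
        off = np.abs(sums - 1.0) > SIMPLEX_TOL
        if np.any(off):
            warnings.warn(
                f"{int(off.sum())} proportion column(s) do not sum to 1 "
                "(unscaled abundances?); renormalizing columns to the simplex",
                stacklevel=2,
            )
            self.values = self.values / sums
        if np.linalg.matrix_rank(self.values) < len(self.celltype_ids):
            raise ValidationError(
                "proportion matrix is row-rank deficient: some cell type is a "
                "linear combination of the others across samples"
            )

    @property
    def n_celltypes(self) -> int:
        return len(self.celltype_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.celltype_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ProportionMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class SignatureMatrix:
    """Signature matrix S: genes x cell types.

    Entries must be finite; non-negativity is a property of particular
    estimators (Rodeo, NNLS), not of the container, since unconstrained
    least squares can legitimately return negative values.
    """

    values: np.ndarray
    gene_ids: list[str]
    celltype_ids: list[str]

    def __post_init__(self) -> None:
        self.gene_ids = _check_ids(self.gene_ids, "gene")
        self.celltype_ids = _check_ids(self.celltype_ids, "cell type")
        if len(self.gene_ids) < 1:
            raise ValidationError("signature matrix needs at least one gene")
        self.values = _as_matrix(
            self.values, len(self.gene_ids), len(self.celltype_ids), "signature"
        )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_celltypes(self) -> int:
        return len(self.celltype_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.gene_ids, columns=self.celltype_ids
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SignatureMatrix":
        return cls(df.to_numpy(dtype=float), list(df.index), list(df.columns))


@dataclass
class DeconvResult:
    """A fitted signature matrix plus per-gene diagnostics.

    ``excluded`` maps each gene to the set of cell types forced to zero by
    Rodeo's negative-coefficient exclusion (empty for OLS/NNLS);
    ``weights`` holds final per-sample Huber weights per gene (Rodeo only).
    """

    signature: SignatureMatrix
    excluded: dict[str, frozenset[str]]
    converged: dict[str, bool]
    method_name: str
    weights: pd.DataFrame | None = field(default=None)

    def __post_init__(self) -> None:
        ct_index = {c: j for j, c in enumerate(self.signature.celltype_ids)}
        gene_index = {g: i for i, g in enumerate(self.signature.gene_ids)}
        for gene, excl in self.excluded.items():
            if not excl:
                continue
            g = gene_index[gene]
            for ct in excl:
                if self.signature.values[g, ct_index[ct]] != 0.0:
                    raise ValidationError(
                        f"excluded cell type {ct!r} of gene {gene!r} has a "
                        "non-zero signature entry"
                    )
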