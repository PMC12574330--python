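"""Readers and writers for the on-disk formats the tool touches.

Expression comes in as a Matrix Market sparse matrix with feature / barcode
TSV sidecars (the de-facto standard layout for droplet and spatial assays)
or as a dense CSV; coordinates as a delimited table with one row per spot.
Spot ordering is positional: row *i* of the coordinate table corresponds to
column *i* of the (features x spots) expression matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .errors import FormatError, ParameterError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "SpotCoordinates",
    "read_expression_mtx",
    "read_expression_csv",
    "read_coordinates",
    "write_expression_mtx",
    "write_coordinates",
    "write_results",
]

#: Columns of the results table, in output order.
RESULT_COLUMNS = [
    "feature_id",
    "var_small",
    "var_big",
    "weight",
    "ratio",
    "p_value",
    "q_value",
]


@dataclass
class ExpressionMatrix:
    """Sparse nonnegative feature-by-spot count matrix.

    Attributes
    ----------
    values
        CSR matrix of shape (n_features, n_spots); all entries finite, >= 0.
    feature_ids, spot_ids
        Unique string identifiers for rows and columns.
    """

    values: sp.csr_matrix
    feature_ids: list[str]
    spot_ids: list[str]

    def __post_init__(self) -> None:
        self.values = sp.csr_matrix(self.values, dtype=np.float64)
        self.values.eliminate_zeros()
        n, m = self.values.shape
        if n < 1 or m < 1:
            raise ValidationError("expression matrix must be at least 1x1")
        if len(self.feature_ids) != n:
            raise FormatError(
                f"{len(self.feature_ids)} feature ids for {n} matrix rows"
            )
        if len(self.spot_ids) != m:
            raise FormatError(f"{len(self.spot_ids)} spot ids for {m} matrix columns")
        if len(set(self.feature_ids)) != n:
            raise ValidationError("duplicate feature ids")
        if len(set(self.spot_ids)) != m:
            raise ValidationError("duplicate spot ids")
        data = self.values.data
        if data.size and (not np.all(np.isfinite(data)) or data.min() < 0):
            raise ValidationError("expression values must be finite and nonnegative")

    @property
    def n_features(self) -> int:
        return self.values.shape[0]

    @property
    def n_spots(self) -> int:
        return self.values.shape[1]

    @property
    def sparsity(self) -> float:
        """Proportion of nonzero entries (the data density S)."""
        return self.values.nnz / (self.n_features * self.n_spots)


@dataclass
class SpotCoordinates:
    """M x D spot coordinates in arbitrary length units, D in {2, 3}."""

    coords: np.ndarray
    dim_names: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=np.float64)
        if self.coords.ndim != 2:
            raise ValidationError("coordinates must be a 2-D array")
        if self.coords.shape[1] not in (2, 3):
            raise ValidationError(
                f"unsupported dimension D={self.coords.shape[1]}; expected 2 or 3"
            )
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if self.dim_names is not None and len(self.dim_names) != self.coords.shape[1]:
            raise ValidationError("dim_names length does not match D")
        # Duplicate locations are legal (multiple cells per bin); just note them.
        n_unique = len({tuple(row) for row in self.coords})
        if n_unique < self.coords.shape[0]:
            logger.info(
                "%d of %d spots share a location with another spot",
                self.coords.shape[0] - n_unique,
                self.coords.shape[0],
            )

    @property
    def n_spots(self) -> int:
        return self.coords.shape[0]

    @property
    def n_dims(self) -> int:
        return self.coords.shape[1]


def _read_id_column(path: Path | str) -> list[str]:
    ids = pd.read_csv(path, sep="\t", header=None, dtype=str).iloc[:, 0]
    return ids.tolist()


def read_expression_mtx(
    matrix_path: Path | str,
    features_path: Path | str,
    barcodes_path: Path | str,
    orientation: str = "features_by_spots",
) -> ExpressionMatrix:
    """Read a Matrix Market matrix plus feature/barcode sidecar files.

    Parameters
    ----------
    orientation
        ``"features_by_spots"`` if on-disk rows are features (the usual
        CellRanger-style layout), ``"spots_by_features"`` if transposed.
        The returned matrix is always features x spots.
    """
    if orientation not in ("features_by_spots", "spots_by_features"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    try:
        mat = scipy.io.mmread(str(matrix_path))
    except Exception as exc:  # scipy raises plain ValueError on bad files
        raise FormatError(f"cannot parse Matrix Market file {matrix_path}: {exc}")
    mat = sp.csr_matrix(mat)
    if orientation == "spots_by_features":
        mat = sp.csr_matrix(mat.T)
    features = _read_id_column(features_path)
    barcodes = _read_id_column(barcodes_path)
    if mat.shape[0] != len(features):
        raise FormatError(
            f"matrix has {mat.shape[0]} feature rows but features file lists "
            f"{len(features)} ids"
        )
    if mat.shape[1] != len(barcodes):
        raise FormatError(
            f"matrix has {mat.shape[1]} spot columns but barcodes file lists "
            f"{len(barcodes)} ids"
        )
    return ExpressionMatrix(mat, features, barcodes)


def read_expression_csv(path: Path | str, orientation: str = "features_by_spots") -> ExpressionMatrix:
    """Read a dense delimited table with feature ids as the index column."""
    if orientation not in ("features_by_spots", "spots_by_features"):
        raise ParameterError(f"unknown orientation {orientation!r}")
    df = pd.read_csv(path, sep=None, engine="python", index_col=0)
    if orientation == "spots_by_features":
        df = df.T
    values = df.to_numpy(dtype=np.float64)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"non-numeric or non-finite values in {path}")
    return ExpressionMatrix(
        sp.csr_matrix(values), [str(i) for i in df.index], [str(c) for c in df.columns]
    )


def read_coordinates(path: Path | str, columns: list[str] | None = None) -> SpotCoordinates:
    """Read an M x D coordinate table (CSV or TSV; D inferred from columns)."""
    df = pd.read_csv(path, sep=None, engine="python")
    if columns is not None:
        missing = [c for c in columns if c not in df.columns]
        if missing:
            raise FormatError(f"columns {missing} not found in {path}")
        df = df[columns]
    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        raise ValidationError(f"non-numeric coordinate cell in {path}")
    if numeric.shape[1] not in (2, 3):
        raise ValidationError(
            f"{numeric.shape[1]} coordinate columns in {path}; select 2 or 3 "
            "with the columns argument"
        )
    return SpotCoordinates(numeric.to_numpy(), dim_names=[str(c) for c in numeric.columns])


def write_expression_mtx(
    X: ExpressionMatrix,
    matrix_path: Path | str,
    features_path: Path | str,
    barcodes_path: Path | str,
) -> None:
    """Write the features x spots sparse matrix with its id sidecars."""
    scipy.io.mmwrite(str(matrix_path), sp.coo_matrix(X.values))
    Path(features_path).write_text("\n".join(X.feature_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(X.spot_ids) + "\n")


def write_coordinates(coords: SpotCoordinates, path: Path | str) -> None:
    names = coords.dim_names or ["xyz"[d] for d in range(coords.n_dims)]
    pd.DataFrame(coords.coords, columns=names).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: Path | str) -> None:
    """Write the per-feature statistic table as CSV at full float precision."""
    if len(table) == 0:
        raise ValidationError("refusing to write an empty results table")
    out = table.reindex(columns=RESULT_COLUMNS)
    out.to_csv(path, index=False, float_format="%.17g")
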