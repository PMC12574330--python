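"""Local means at two granularities and the variance-ratio statistic.

For feature j and patch matrix B(k), the local mean at spot i is the average
of the scaled expression over the patch of i. The statistic

    r_j = w_j * var(local means, big radius) / var(local means, small radius)

measures how slowly the variance of the smoothed expression field decays as
the smoothing scale grows: a spatially structured feature keeps variance at
the coarse scale, inflating r_j, while an unstructured feature's local means
regress quickly to the global mean. The weight w_j = var_j / max_n var_n
normalizes by the intrinsic expression variance so that high-variance
features do not dominate purely by amplitude.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .errors import DegenerateInputError, ParameterError, ValidationError
from .io import ExpressionMatrix, SpotCoordinates
from .neighborhood import NeighborParams, PatchMatrix, build_patch_pair
from .preprocessing import ScaledExpression, rescale_coordinates, scale_expression_maxabs

logger = logging.getLogger(__name__)

__all__ = [
    "LocalMeans",
    "local_means",
    "variance_of_local_means",
    "compute_weights",
    "variance_ratio_statistic",
    "compute_statistics",
]

DEFAULT_BLOCK_SIZE = 2048


@dataclass
class LocalMeans:
    """N x M matrix of patch-averaged scaled expression; entries in [0, 1]."""

    means: np.ndarray
    radius_tag: str  # "small" or "big"


def _column_normalized_patches(patches: PatchMatrix) -> sp.csr_matrix:
    """B(k)^T with columns divided by patch size: column i = b_i / ||b_i||_1.

    Multiplying the scaled expression by this matrix yields the local means.
    """
    sizes = patches.patch_sizes().astype(np.float64)
    # row-scale B by 1/size, then transpose: (Diag(1/size) B)^T = B^T Diag(1/size)
    return sp.csr_matrix(sp.diags(1.0 / sizes) @ patches.indicator).T.tocsc()


def local_means(X_scaled: ScaledExpression, patches: PatchMatrix, radius_tag: str = "small") -> LocalMeans:
    """Average scaled expression over each spot's patch, X~ . B^T . Diag(1/|b_i|).

    Returns a dense N x M array; the variance pipeline uses the block-wise
    path instead and never materializes this for large N.
    """
    if X_scaled.values.shape[1] != patches.n_spots:
        raise ValidationError(
            f"expression has {X_scaled.values.shape[1]} spots but patch matrix "
            f"has {patches.n_spots}"
        )
    bt = _column_normalized_patches(patches)
    means = np.asarray((X_scaled.values @ bt).todense())
    return LocalMeans(means, radius_tag=radius_tag)


def variance_of_local_means(lm: LocalMeans) -> np.ndarray:
    """Per-feature sample variance (ddof=1) of the local means across spots."""
    if lm.means.shape[1] < 2:
        raise ValidationError("variance needs at least 2 spots")
    return np.var(lm.means, axis=1, ddof=1)


def _sparse_row_variances(values: sp.csr_matrix, ddof: int = 1) -> np.ndarray:
    """Sample variance of each row of a sparse matrix, zeros included."""
    m = values.shape[1]
    if m <= ddof:
        raise ValidationError("variance needs more spots than ddof")
    s1 = np.asarray(values.sum(axis=1)).ravel()
    s2 = np.asarray(values.multiply(values).sum(axis=1)).ravel()
    var = (s2 - s1 * s1 / m) / (m - ddof)
    return np.maximum(var, 0.0)  # clamp tiny negative rounding residue


def compute_weights(
    X: ExpressionMatrix | ScaledExpression, variance_source: str = "raw"
) -> np.ndarray:
    """Intrinsic-variance weights w_j = var_j / max_n var_n, in [0, 1].

    ``variance_source="raw"`` (default) uses the raw counts;
    ``"scaled"`` uses the max-abs-scaled matrix instead.
    """
    if variance_source not in ("raw", "scaled"):
        raise ParameterError(f"unknown variance_source {variance_source!r}")
    if variance_source == "scaled" and isinstance(X, ExpressionMatrix):
        X = scale_expression_maxabs(X)
    var = _sparse_row_variances(sp.csr_matrix(X.values))
    vmax = var.max() if var.size else 0.0
    if vmax == 0.0:
        raise DegenerateInputError(
            "every feature is constant across spots; no spatial statistic is defined"
        )
    return var / vmax


def variance_ratio_statistic(
    var_small: np.ndarray, var_big: np.ndarray, weights: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Weighted big/small variance ratio r_j with degeneracy flags.

    Returns ``(ratios, undefined_mask, infinite_mask)``:

    * ``var_small > 0``: r_j = w_j * var_big / var_small (the regular case);
    * ``var_small == var_big == 0`` (constant local means, e.g. all-zero
      feature): ratio NaN, ``undefined_mask`` set — convention p = 1;
    * ``var_small == 0 < var_big``: ratio +inf, ``infinite_mask`` set —
      maximal significance, excluded from null fitting.
    """
    var_small = np.asarray(var_small, dtype=np.float64)
    var_big = np.asarray(var_big, dtype=np.float64)
    weights = np.asarray(weights, dtype=np.float64)
    if not (var_small.shape == var_big.shape == weights.shape):
        raise ValidationError("var_small, var_big, weights must have equal length")
    if (var_small < 0).any() or (var_big < 0).any() or (weights < 0).any():
        raise ValidationError("variances and weights must be nonnegative")
    undefined = (var_small == 0) & (var_big == 0)
    infinite = (var_small == 0) & (var_big > 0)
    regular = var_small > 0
    ratios = np.full(var_small.shape, np.nan)
    ratios[regular] = weights[regular] * var_big[regular] / var_small[regular]
    ratios[infinite] = np.inf
    return ratios, undefined, infinite


def _blockwise_local_mean_variances(
    X_scaled: ScaledExpression,
    small: PatchMatrix,
    big: PatchMatrix,
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Variances of small- and big-patch local means, in feature blocks.

    Peak memory is O(block_size x M); results are block-size independent.
    """
    bt_small = _column_normalized_patches(small)
    bt_big = _column_normalized_patches(big)
    n = X_scaled.values.shape[0]
    var_s = np.empty(n)
    var_b = np.empty(n)
    for start in range(0, n, block_size):
        stop = min(start + block_size, n)
        block = X_scaled.values[start:stop]
        var_s[start:stop] = np.var(np.asarray((block @ bt_small).todense()), axis=1, ddof=1)
        var_b[start:stop] = np.var(np.asarray((block @ bt_big).todense()), axis=1, ddof=1)
    return var_s, var_b


def compute_statistics(
    X: ExpressionMatrix,
    coords: SpotCoordinates,
    params: NeighborParams | None = None,
    variance_source: str = "raw",
    block_size: int = DEFAULT_BLOCK_SIZE,
) -> pd.DataFrame:
    """Run the full statistic pipeline; p/q columns are left NaN (pending).

    Steps: density-normalize coordinates, max-abs scale expression, build the
    paired patch matrices, compute local-mean variances at both radii, weight
    by intrinsic variance, and form the ratio. One output row per input
    feature, input order preserved.
    """
    params = params or NeighborParams()
    if X.n_spots != coords.n_spots:
        raise ValidationError(
            f"expression has {X.n_spots} spots but coordinates have {coords.n_spots}"
        )
    rescaled = rescale_coordinates(coords)
    scaled = scale_expression_maxabs(X)
    small, big = build_patch_pair(rescaled, params)
    var_s, var_b = _blockwise_local_mean_variances(scaled, small, big, block_size)
    weights = compute_weights(X if variance_source == "raw" else scaled, variance_source)
    ratios, undefined, infinite = variance_ratio_statistic(var_s, var_b, weights)
    raw_var = _sparse_row_variances(X.values)
    return pd.DataFrame(
        {
            "feature_id": X.feature_ids,
            "var_small": var_s,
            "var_big": var_b,
            "raw_var": raw_var,
            "weight": weights,
            "ratio": ratios,
            "undefined": undefined,
            "infinite": infinite,
            "p_value": np.nan,
            "q_value": np.nan,
        }
    )
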