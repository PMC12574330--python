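"""Radius-bounded neighbor patches as sparse binary indicator matrices.

A spot's "patch" at radius R is the set of other spots strictly within
Euclidean distance R. A spot with no neighbor at that radius falls back to
a self-patch (the diagonal entry is set), so local means are always defined.
Two backends: an exact KD-tree radius search (the default; must match the
brute-force all-pairs answer bit-for-bit) and an approximate search that may
miss neighbors in a thin shell below the radius but never admits a spot
beyond it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree

from .errors import ParameterError
from .preprocessing import RescaledCoordinates

logger = logging.getLogger(__name__)

__all__ = ["NeighborParams", "PatchMatrix", "build_patch_matrix", "build_patch_pair"]

BACKENDS = ("exact_kdtree", "approximate")


@dataclass
class NeighborParams:
    """Paired patch radii in density-normalized units (defaults 1 and 3)."""

    r_small: float = 1.0
    r_big: float = 3.0
    backend: str = "exact_kdtree"
    ann_accuracy: float = 1.0  # approximate-backend recall knob, in (0, 1]

    def __post_init__(self) -> None:
        if self.r_small <= 0 or self.r_big <= 0:
            raise ParameterError("patch radii must be positive")
        if self.r_small >= self.r_big:
            raise ParameterError(
                f"r_small ({self.r_small}) must be smaller than r_big ({self.r_big})"
            )
        if self.backend not in BACKENDS:
            raise ParameterError(f"unknown backend {self.backend!r}")
        if not 0 < self.ann_accuracy <= 1:
            raise ParameterError("ann_accuracy must be in (0, 1]")


@dataclass
class PatchMatrix:
    """Sparse binary M x M indicator; row i is the patch of spot i."""

    indicator: sp.csr_matrix
    radius: float
    backend: str
    fallback_rows: frozenset[int] = field(default_factory=frozenset)

    @property
    def n_spots(self) -> int:
        return self.indicator.shape[0]

    def patch_sizes(self) -> np.ndarray:
        """L1 norm of each row (number of spots averaged per patch)."""
        return np.diff(self.indicator.indptr)


def _neighbor_lists_exact(coords: np.ndarray, radius: float) -> list[np.ndarray]:
    """All pairs strictly within `radius`, via KD-tree + squared-distance filter.

    query_pairs uses a closed ball (<= r); ties at exactly r are removed by
    comparing squared distances, avoiding sqrt rounding.
    """
    tree = cKDTree(coords)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    if len(pairs):
        d2 = np.einsum(
            "ij,ij->i",
            coords[pairs[:, 0]] - coords[pairs[:, 1]],
            coords[pairs[:, 0]] - coords[pairs[:, 1]],
        )
        pairs = pairs[d2 < radius * radius]
    m = coords.shape[0]
    rows = np.concatenate([pairs[:, 0], pairs[:, 1]]) if len(pairs) else np.empty(0, int)
    cols = np.concatenate([pairs[:, 1], pairs[:, 0]]) if len(pairs) else np.empty(0, int)
    order = np.argsort(rows, kind="stable")
    rows, cols = rows[order], cols[order]
    counts = np.bincount(rows, minlength=m)
    splits = np.cumsum(counts)[:-1]
    return [np.sort(c) for c in np.split(cols, splits)]


def _neighbor_lists_approx(
    coords: np.ndarray, radius: float, ann_accuracy: float
) -> list[np.ndarray]:
    """eps-relaxed KD-tree ball query with exact post-filtering.

    The relaxed query may prune branches containing points at distance in
    (radius / (1 + eps), radius); those neighbors can be missed. Candidates
    beyond the radius returned by the bulk-acceptance path are removed by an
    exact squared-distance check, so precision is always 1.
    """
    eps = 1.0 / ann_accuracy - 1.0
    tree = cKDTree(coords)
    lists = tree.query_ball_point(coords, radius, eps=eps)
    r2 = radius * radius
    out = []
    for i, cand in enumerate(lists):
        cand = np.asarray(cand, dtype=np.int64)
        diffs = coords[cand] - coords[i]
        keep = np.einsum("ij,ij->i", diffs, diffs) < r2
        cand = cand[keep]
        out.append(np.sort(cand[cand != i]))
    return out


def build_patch_matrix(
    coords: RescaledCoordinates | np.ndarray,
    radius: float,
    backend: str = "exact_kdtree",
    ann_accuracy: float = 1.0,
) -> PatchMatrix:
    """Build the binary patch matrix B(R) for one radius."""
    if radius <= 0:
        raise ParameterError("radius must be positive")
    if backend not in BACKENDS:
        raise ParameterError(f"unknown backend {backend!r}")
    arr = coords.coords if isinstance(coords, RescaledCoordinates) else np.asarray(coords)
    m = arr.shape[0]
    if backend == "exact_kdtree":
        lists = _neighbor_lists_exact(arr, radius)
    else:
        lists = _neighbor_lists_approx(arr, radius, ann_accuracy)
    fallback = frozenset(i for i, nb in enumerate(lists) if nb.size == 0)
    if fallback:
        logger.info(
            "%d/%d spots have no neighbor within radius %.3g; self-patch fallback",
            len(fallback),
            m,
            radius,
        )
    indptr = np.zeros(m + 1, dtype=np.int64)
    indices = []
    for i, nb in enumerate(lists):
        if nb.size == 0:
            nb = np.array([i], dtype=np.int64)  # self-patch fallback
        indices.append(nb)
        indptr[i + 1] = indptr[i] + nb.size
    indices = np.concatenate(indices)
    data = np.ones(indices.size, dtype=np.float64)
    indicator = sp.csr_matrix((data, indices, indptr), shape=(m, m))
    return PatchMatrix(indicator, radius=radius, backend=backend, fallback_rows=fallback)


def build_patch_pair(
    coords: RescaledCoordinates | np.ndarray, params: NeighborParams
) -> tuple[PatchMatrix, PatchMatrix]:
    """Build the (small, big) patch matrices on identical coordinates."""
    small = build_patch_matrix(coords, params.r_small, params.backend, params.ann_accuracy)
    big = build_patch_matrix(coords, params.r_big, params.backend, params.ann_accuracy)
    return small, big
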