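"""Independent dense, loop-based reimplementation of the statistic pipeline.

Deliberately naive: dense arrays, an explicit all-pairs distance matrix and
per-spot loops, no sparse algebra and no KD-tree. Used only as an oracle to
validate the package's sparse pipeline; it must stay independent of the
code paths it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import norm


def dense_rescale(coords: np.ndarray) -> np.ndarray:
    ranges = coords.max(axis=0) - coords.min(axis=0)
    eff = ranges > 0
    factor = (coords.shape[0] / np.prod(ranges[eff])) ** (1.0 / eff.sum())
    return coords * factor


def dense_patches(coords: np.ndarray, radius: float) -> np.ndarray:
    """Binary M x M patch matrix by brute-force thresholding, with fallback."""
    m = coords.shape[0]
    d2 = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2)
    b = (d2 < radius * radius).astype(float)
    np.fill_diagonal(b, 0.0)
    for i in range(m):
        if b[i].sum() == 0:
            b[i, i] = 1.0
    return b


def dense_pipeline(
    X: np.ndarray,
    coords: np.ndarray,
    r_small: float = 1.0,
    r_big: float = 3.0,
    rescale: bool = True,
    ddof: int = 1,
):
    """Full pipeline on dense arrays; returns (ratios, pvalues).

    Mirrors the method definition step by step: max-abs scaling, strict
    radius patches with self-fallback, patch-mean loops, per-feature
    variances, raw-variance weights, weighted variance ratio, lognormal
    fit over finite positive ratios, upper-tail p-values.
    """
    n, m = X.shape
    sc = dense_rescale(coords) if rescale else coords
    maxima = X.max(axis=1)
    Xs = X / np.where(maxima == 0, 1.0, maxima)[:, None]
    ratios = np.empty(n)
    variances = {}
    for tag, radius in (("s", r_small), ("b", r_big)):
        b = dense_patches(sc, radius)
        means = np.empty((n, m))
        for i in range(m):
            patch = np.flatnonzero(b[i])
            means[:, i] = Xs[:, patch].mean(axis=1)
        variances[tag] = np.var(means, axis=1, ddof=ddof)
    raw_var = np.var(X, axis=1, ddof=ddof)
    weights = raw_var / raw_var.max()
    vs, vb = variances["s"], variances["b"]
    ratios = np.full(n, np.nan)
    for j in range(n):
        if vs[j] > 0:
            ratios[j] = weights[j] * vb[j] / vs[j]
        elif vb[j] > 0:
            ratios[j] = np.inf
    ok = np.isfinite(ratios) & (ratios > 0)
    logs = np.log(ratios[ok])
    mu, sigma = logs.mean(), logs.std(ddof=1)
    p = np.ones(n)
    p[ok] = norm.sf((np.log(ratios[ok]) - mu) / sigma)
    p[np.isposinf(ratios)] = 0.0
    return ratios, p
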