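"""Lognormal null model, p-values, permutation null, FDR and meta-analysis.

Under the null of no spatial structure the variance ratio r_j is
approximately lognormal across features; with most features non-spatial,
the null is fitted directly to all finite ratios (log-moment MLE) and each
feature gets a one-sided p-value from the upper tail. Low-throughput panels
(few hundred features) instead estimate the null from randomly permuted
features, which destroys spatial alignment while preserving the value
distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .errors import InsufficientNullError, ParameterError, ValidationError
from .io import ExpressionMatrix, SpotCoordinates
from .neighborhood import NeighborParams
from .statistic import compute_statistics

logger = logging.getLogger(__name__)

__all__ = [
    "LognormalNull",
    "MetaResult",
    "fit_lognormal_null",
    "pvalues_from_null",
    "permutation_null",
    "adjust_bh",
    "stouffer_combine",
    "call_svfs",
    "detect_svfs",
]

MIN_NULL_FEATURES = 10
#: Below this many features the all-features null is unreliable and a
#: permutation null is recommended (low-throughput panel heuristic).
LOW_THROUGHPUT_THRESHOLD = 1000


@dataclass
class LognormalNull:
    """Fitted null for log r: mean ``mu_log``, sd ``sigma_log`` (> 0)."""

    mu_log: float
    sigma_log: float
    n_fit: int
    source: str = "all_features"  # or "permutation"


@dataclass
class MetaResult:
    """Stouffer-combined one-sided p-value across samples for one feature."""

    feature_id: str
    per_sample_p: list[float]
    combined_p: float
    single_sample: bool = False


def fit_lognormal_null(
    ratios: np.ndarray,
    exclude: np.ndarray | None = None,
    trim_fraction: float = 0.0,
    source: str = "all_features",
) -> LognormalNull:
    """Fit mu_log / sigma_log as sample mean and sd of log r.

    ``exclude`` masks features whose statistic is degenerate (undefined or
    infinite); nonpositive and nonfinite ratios are always dropped.
    ``trim_fraction`` optionally discards that fraction of the largest
    ratios before fitting (default 0: untrimmed).
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    if exclude is not None:
        ratios = ratios[~np.asarray(exclude, dtype=bool)]
    ratios = ratios[np.isfinite(ratios) & (ratios > 0)]
    if not 0 <= trim_fraction < 0.5:
        raise ParameterError("trim_fraction must be in [0, 0.5)")
    if trim_fraction > 0:
        cut = np.quantile(ratios, 1.0 - trim_fraction)
        ratios = ratios[ratios <= cut]
    if ratios.size < MIN_NULL_FEATURES:
        raise InsufficientNullError(
            f"only {ratios.size} usable ratios (< {MIN_NULL_FEATURES}); "
            "use the permutation null for small feature panels"
        )
    logs = np.log(ratios)
    sigma = float(np.std(logs, ddof=1))
    if sigma == 0.0:
        raise InsufficientNullError(
            "all ratios identical; null distribution has no spread"
        )
    return LognormalNull(
        mu_log=float(np.mean(logs)), sigma_log=sigma, n_fit=int(ratios.size), source=source
    )


def pvalues_from_null(ratios: np.ndarray, null: LognormalNull) -> np.ndarray:
    """One-sided upper-tail p-values, p_j = 1 - Phi((log r_j - mu)/sigma).

    Degenerate statistics follow the fixed conventions: undefined (NaN)
    ratios get p = 1, infinite ratios get p = 0.
    """
    ratios = np.asarray(ratios, dtype=np.float64)
    p = np.ones(ratios.shape)
    finite = np.isfinite(ratios) & (ratios > 0)
    z = (np.log(ratios[finite]) - null.mu_log) / null.sigma_log
    p[finite] = norm.sf(z)
    p[np.isposinf(ratios)] = 0.0
    # exact zeros (possible only if var_big == 0 < var_small) sit at the
    # bottom of the scale: no evidence of structure
    p[ratios == 0] = 1.0
    return p


def permutation_null(
    X: ExpressionMatrix,
    coords: SpotCoordinates,
    params: NeighborParams | None = None,
    n_null_features: int = 1000,
    seed: int = 0,
    variance_source: str = "raw",
) -> LognormalNull:
    """Estimate the null from features permuted across spot positions.

    Samples ``n_null_features`` features (with replacement when more than N
    are requested), independently shuffles each across spots, recomputes the
    variance ratio on the permuted matrix, and fits the lognormal to those
    ratios. Fully reproducible given ``seed``.
    """
    if n_null_features < MIN_NULL_FEATURES:
        raise ParameterError(f"n_null_features must be >= {MIN_NULL_FEATURES}")
    rng = np.random.default_rng(seed)
    replace = n_null_features > X.n_features
    chosen = rng.choice(X.n_features, size=n_null_features, replace=replace)
    dense = np.asarray(X.values[chosen].todense())
    for row in dense:  # independent permutation per feature
        rng.shuffle(row)
    permuted = ExpressionMatrix(
        sp.csr_matrix(dense),
        [f"null_{i}" for i in range(n_null_features)],
        list(X.spot_ids),
    )
    table = compute_statistics(permuted, coords, params, variance_source=variance_source)
    return fit_lognormal_null(
        table["ratio"].to_numpy(),
        exclude=(table["undefined"] | table["infinite"]).to_numpy(),
        source="permutation",
    )


def adjust_bh(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValidationError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def stouffer_combine(
    p_lists: dict[str, list[float]] | pd.DataFrame,
) -> list[MetaResult]:
    """Combine one-sided p-values across samples with Stouffer's method.

    z_i = Phi^{-1}(1 - p_i); combined z = sum z_i / sqrt(k); combined
    p = 1 - Phi(z), unweighted. Inputs of exactly 0 or 1 are clamped to the
    open interval with a warning; a feature observed in a single sample is
    returned unchanged with ``single_sample=True``.
    """
    if isinstance(p_lists, pd.DataFrame):
        p_lists = {
            str(fid): [p for p in row if np.isfinite(p)]
            for fid, row in p_lists.iterrows()
        }
    tiny = np.finfo(np.float64).tiny
    results = []
    for fid, ps in p_lists.items():
        ps = [p for p in ps if np.isfinite(p)]
        if any(p < 0 or p > 1 for p in ps):
            raise ValidationError(f"p-values out of [0, 1] for feature {fid}")
        if any(p == 0 or p == 1 for p in ps):
            logger.warning("feature %s: p of exactly 0/1 clamped for Stouffer", fid)
            ps = [min(max(p, tiny), 1.0 - 1e-16) for p in ps]
        if len(ps) == 0:
            continue
        if len(ps) == 1:
            results.append(MetaResult(fid, ps, ps[0], single_sample=True))
            continue
        z = norm.isf(np.asarray(ps))
        combined = float(norm.sf(z.sum() / np.sqrt(len(ps))))
        results.append(MetaResult(fid, ps, combined))
    return results


def call_svfs(table: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Flag features with p < alpha as spatially variable."""
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    if table["p_value"].isna().any():
        raise ValidationError("p-values missing; run inference first")
    out = table.copy()
    out["significant"] = out["p_value"] < alpha
    logger.info("%d features significant at alpha=%g", int(out["significant"].sum()), alpha)
    return out


def detect_svfs(
    X: ExpressionMatrix,
    coords: SpotCoordinates,
    params: NeighborParams | None = None,
    alpha: float = 0.05,
    variance_source: str = "raw",
    null_mode: str = "all_features",
    n_null_features: int = 1000,
    seed: int = 0,
    fdr: bool = False,
) -> pd.DataFrame:
    """End-to-end detection: statistics, null fit, p-values, optional BH q.

    The library-level driver behind the ``detect`` CLI subcommand.
    """
    if null_mode not in ("all_features", "permutation"):
        raise ParameterError(f"unknown null_mode {null_mode!r}")
    table = compute_statistics(X, coords, params, variance_source=variance_source)
    if null_mode == "all_features" and X.n_features < LOW_THROUGHPUT_THRESHOLD:
        logger.warning(
            "only %d features: the all-features null may be unreliable; "
            "consider null_mode='permutation'",
            X.n_features,
        )
    if null_mode == "permutation":
        null = permutation_null(
            X, coords, params, n_null_features=n_null_features, seed=seed,
            variance_source=variance_source,
        )
    else:
        null = fit_lognormal_null(
            table["ratio"].to_numpy(),
            exclude=(table["undefined"] | table["infinite"]).to_numpy(),
        )
    logger.info(
        "fitted %s null: mu_log=%.4f sigma_log=%.4f on %d features",
        null.source, null.mu_log, null.sigma_log, null.n_fit,
    )
    table["p_value"] = pvalues_from_null(table["ratio"].to_numpy(), null)
    table["q_value"] = adjust_bh(table["p_value"].to_numpy()) if fdr else np.nan
    return call_svfs(table, alpha=alpha)
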