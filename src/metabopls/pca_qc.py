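"""Exploratory PCA with Hotelling T2 and DModX outlier screening.

PCA is computed by SVD of the autoscaled matrix (deterministic, equivalent
to converged NIPALS). The T2 and DModX critical values follow the standard
SIMCA-style F-distribution formulas; the constants are spelled out in the
docstrings below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateModelError

#: default cumulative explained-variance target used when K is not given
DEFAULT_VARIANCE_TARGET = 0.60


@dataclass
class PCAModel:
    """Truncated principal-component model of an autoscaled matrix."""

    n_components: int
    scores: np.ndarray  # (n, K)
    loadings: np.ndarray  # (p, K), orthonormal columns
    explained_variance_ratio: np.ndarray  # (K,)
    cumulative_r2x: float
    n_samples: int
    n_features: int


def fit_pca(Z: np.ndarray, K: int | float | None = None) -> PCAModel:
    """Fit a K-component PCA to the autoscaled matrix Z.

    ``K`` may be an explicit component count, a cumulative explained-variance
    target in (0, 1), or None (target ``DEFAULT_VARIANCE_TARGET``). The sign
    of each component is fixed so its largest-magnitude loading is positive.
    """
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    max_k = min(n - 1, p)
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    total = float(np.sum(s**2))
    if total == 0:
        raise DegenerateModelError("matrix has no variance")
    ratios = s**2 / total
    if K is None:
        K = DEFAULT_VARIANCE_TARGET
    if isinstance(K, float) and 0 < K < 1:
        K = int(np.searchsorted(np.cumsum(ratios[:max_k]), K) + 1)
        K = min(K, max_k)
    K = int(K)
    if not 1 <= K <= max_k:
        raise DegenerateModelError(f"K={K} outside the valid range [1, {max_k}]")
    loadings = Vt[:K].T
    scores = U[:, :K] * s[:K]
    # deterministic sign: largest-|loading| entry positive per component
    for a in range(K):
        j = int(np.argmax(np.abs(loadings[:, a])))
        if loadings[j, a] < 0:
            loadings[:, a] *= -1
            scores[:, a] *= -1
    return PCAModel(
        n_components=K,
        scores=scores,
        loadings=loadings,
        explained_variance_ratio=ratios[:K],
        cumulative_r2x=float(ratios[:K].sum()),
        n_samples=n,
        n_features=p,
    )


@dataclass
class QCStats:
    """Per-observation outlier statistics against a PCA model."""

    statistic: np.ndarray
    critical_value: float
    flags: np.ndarray
    alpha: float
    kind: str  # "hotelling_t2" or "dmodx"


def hotelling_t2(model: PCAModel, alpha: float = 0.01) -> QCStats:
    """Hotelling T2 of each observation in the model's score space.

    T2_i = sum_a t_ia^2 / var(t_a), with the per-component score variance
    using denominator n - 1. The critical value is
    K (n - 1)(n + 1) / (n (n - K)) * F_{1-alpha}(K, n - K).
    """
    if not 0 < alpha < 1:
        raise DegenerateModelError("alpha must lie in (0, 1)")
    n, K = model.n_samples, model.n_components
    if n <= K:
        raise DegenerateModelError("T2 threshold undefined for n <= K")
    score_var = model.scores.var(axis=0, ddof=1)
    if np.any(score_var <= 0):
        raise DegenerateModelError("a score component has zero variance")
    t2 = np.sum(model.scores**2 / score_var, axis=1)
    crit = (
        K * (n - 1) * (n + 1) / (n * (n - K)) * stats.f.ppf(1 - alpha, K, n - K)
    )
    return QCStats(
        statistic=t2,
        critical_value=float(crit),
        flags=t2 > crit,
        alpha=alpha,
        kind="hotelling_t2",
    )


def dmodx(Z: np.ndarray, model: PCAModel, alpha: float = 0.01) -> QCStats:
    """Normalized distance-to-model of each observation in predictor space.

    With residuals E = Z - T P', per-observation residual SD
    s_i = sqrt(sum_j e_ij^2 / (p - K)), pooled
    s_0 = sqrt(sum_ij e_ij^2 / ((n - K - 1)(p - K))), DModX_i = s_i / s_0,
    and critical value sqrt(F_{1-alpha}(p - K, (n - K - 1)(p - K))).

    Observations of the training matrix are shrunk by the standard
    training-set correction sqrt(n / (n - K - 1)) (their residuals are
    deflated by having been fitted); the factor tends to 1 as n grows, so
    large-sample calibration is unaffected.
    """
    if not 0 < alpha < 1:
        raise DegenerateModelError("alpha must lie in (0, 1)")
    Z = np.asarray(Z, dtype=float)
    n, p = Z.shape
    K = model.n_components
    if p <= K:
        raise DegenerateModelError("DModX degenerate: residual space is empty (p <= K)")
    residuals = Z - model.scores @ model.loadings.T
    ss_rows = np.sum(residuals**2, axis=1)
    total_ss = float(np.sum(Z**2))
    s0_sq = float(ss_rows.sum()) / ((n - K - 1) * (p - K))
    if s0_sq == 0 or (total_ss > 0 and ss_rows.sum() / total_ss < 1e-20):
        return QCStats(
            statistic=np.zeros(n),
            critical_value=float(
                np.sqrt(stats.f.ppf(1 - alpha, p - K, (n - K - 1) * (p - K)))
            ),
            flags=np.zeros(n, dtype=bool),
            alpha=alpha,
            kind="dmodx",
        )
    d = np.sqrt(ss_rows / (p - K) / s0_sq) / np.sqrt(n / (n - K - 1))
    crit = float(np.sqrt(stats.f.ppf(1 - alpha, p - K, (n - K - 1) * (p - K))))
    return QCStats(
        statistic=d, critical_value=crit, flags=d > crit, alpha=alpha, kind="dmodx"
    )
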