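"""Univariate-response PLS (PLS1) by NIPALS, with VIP scores and fit statistics.

The NIPALS recursion for a univariate response needs no inner iteration:
on the deflated pair (X_{a-1}, y_{a-1}),

    w_a = X'y / ||X'y||        (unit-norm weight)
    t_a = X w_a                (score)
    p_a = X't_a / (t_a't_a)    (X loading)
    q_a = y't_a / (t_a't_a)    (y loading)
    X_a = X - t_a p_a',  y_a = y - q_a t_a

and the coefficient vector on the model scale is b = W (P'W)^{-1} q.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, SchemaError
from .preprocess import ScalingParams, autoscale

_RANK_TOL = 1e-12


@dataclass
class PLSModel:
    """A fitted PLS1 model together with its centering/scaling parameters."""

    A: int
    W: np.ndarray  # (p_model, A) unit-norm weights
    T: np.ndarray  # (n, A) scores
    P: np.ndarray  # (p_model, A) X loadings
    q: np.ndarray  # (A,) y loadings
    coef: np.ndarray  # (p_model,) regression coefficients on the model scale
    x_scaler: ScalingParams | None  # None when fitted on pre-scaled data
    y_mean: float
    y_sd: float
    fitted: np.ndarray  # (n,) fitted responses on the original (percent) scale
    n_input_features: int

    @property
    def n_samples(self) -> int:
        return self.T.shape[0]

    @property
    def n_model_features(self) -> int:
        return self.W.shape[0]


def _nipals_pls1(Z: np.ndarray, y: np.ndarray, A: int):
    n, p = Z.shape
    W = np.empty((p, A))
    T = np.empty((n, A))
    P = np.empty((p, A))
    q = np.empty(A)
    X_res = Z.copy()
    y_res = y.astype(float).copy()
    scale0 = max(float(np.linalg.norm(Z.T @ y)), 1.0)
    for a in range(A):
        cov = X_res.T @ y_res
        norm = float(np.linalg.norm(cov))
        if norm <= _RANK_TOL * scale0:
            raise DegenerateModelError(
                f"rank exhausted after {a} component(s); requested A={A}"
            )
        w = cov / norm
        t = X_res @ w
        tt = float(t @ t)
        if tt <= _RANK_TOL:
            raise DegenerateModelError(
                f"rank exhausted after {a} component(s); requested A={A}"
            )
        p_a = X_res.T @ t / tt
        q_a = float(y_res @ t) / tt
        X_res -= np.outer(t, p_a)
        y_res -= q_a * t
        W[:, a], T[:, a], P[:, a], q[a] = w, t, p_a, q_a
    coef = W @ np.linalg.solve(P.T @ W, q)
    return W, T, P, q, coef


def fit_pls1(
    Z: np.ndarray,
    y_scaled: np.ndarray,
    A: int,
    *,
    x_scaler: ScalingParams | None = None,
    y_mean: float = 0.0,
    y_sd: float = 1.0,
) -> PLSModel:
    """Fit an A-component PLS1 model to data already on the model scale.

    ``x_scaler``/``y_mean``/``y_sd`` record how the inputs were brought to
    the model scale so :func:`predict` can map new raw observations; the
    defaults declare the inputs as-is.
    """
    Z = np.asarray(Z, dtype=float)
    y_scaled = np.asarray(y_scaled, dtype=float).ravel()
    n, p = Z.shape
    if y_scaled.shape != (n,):
        raise SchemaError("response length does not match the number of rows")
    if not 1 <= A <= min(n - 1, p):
        raise DegenerateModelError(
            f"A={A} outside the valid range [1, {min(n - 1, p)}]"
        )
    W, T, P, q, coef = _nipals_pls1(Z, y_scaled, A)
    fitted = y_mean + y_sd * (Z @ coef)
    return PLSModel(
        A=A,
        W=W,
        T=T,
        P=P,
        q=q,
        coef=coef,
        x_scaler=x_scaler,
        y_mean=float(y_mean),
        y_sd=float(y_sd),
        fitted=fitted,
        n_input_features=x_scaler.n_input_features if x_scaler is not None else p,
    )


def fit_autoscaled_pls1(X: np.ndarray, y: np.ndarray, A: int) -> PLSModel:
    """Autoscale raw abundances and the percent response, then fit PLS1.

    Zero-variance predictor columns are dropped (recorded in the scaler);
    a zero-variance response is an error.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    Z, scaler = autoscale(X)
    y_mean = float(y.mean())
    y_sd = float(y.std(ddof=1))
    if y_sd == 0:
        raise DegenerateModelError("response has zero variance")
    return fit_pls1(
        Z, (y - y_mean) / y_sd, A, x_scaler=scaler, y_mean=y_mean, y_sd=y_sd
    )


def predict(model: PLSModel, X_new: np.ndarray) -> np.ndarray:
    """Predict the response (original percent scale) for raw new observations.

    Out-of-range predictions are returned unclipped; callers may flag them.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim == 1:
        X_new = X_new.reshape(1, -1)
    if model.x_scaler is not None:
        Z_new = model.x_scaler.transform(X_new)
    else:
        if X_new.shape[1] != model.n_model_features:
            raise SchemaError(
                f"expected {model.n_model_features} features, got {X_new.shape[1]}"
            )
        Z_new = X_new
    return model.y_mean + model.y_sd * (Z_new @ model.coef)


@dataclass
class VIPProfile:
    """Per-feature variable importance in projection.

    ``vip`` is indexed by the model's input feature space; features the
    scaler dropped carry VIP 0 and are listed in ``dropped``. The squared
    VIPs of the modeled features average to 1 (sum = n modeled features).
    """

    vip: np.ndarray
    ssy_per_component: np.ndarray
    A: int
    dropped: np.ndarray


def vip(model: PLSModel) -> VIPProfile:
    """VIP_j = sqrt(p * sum_a SSY_a w_ja^2 / sum_a SSY_a), SSY_a = q_a^2 t_a't_a."""
    ssy = model.q**2 * np.einsum("ia,ia->a", model.T, model.T)
    total = float(ssy.sum())
    if total <= 0:
        raise DegenerateModelError("model explains no response variance (sum SSY = 0)")
    p = model.n_model_features
    scores = np.sqrt(p * (model.W**2 @ ssy) / total)
    if model.x_scaler is not None:
        full = np.zeros(model.n_input_features)
        full[model.x_scaler.keep] = scores
        dropped = model.x_scaler.dropped
    else:
        full = scores
        dropped = np.empty(0, dtype=int)
    return VIPProfile(vip=full, ssy_per_component=ssy, A=model.A, dropped=dropped)


def fit_stats(model: PLSModel, y: np.ndarray) -> tuple[float, float]:
    """Training R2 and RMSEC (denominator n) on the percent scale."""
    y = np.asarray(y, dtype=float).ravel()
    if y.shape != model.fitted.shape:
        raise SchemaError("response length does not match the fitted values")
    residuals = y - model.fitted
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss == 0:
        raise DegenerateModelError("R2 undefined: response has zero variance")
    rss = float(residuals @ residuals)
    return 1.0 - rss / tss, float(np.sqrt(rss / y.size))
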