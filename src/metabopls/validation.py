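"""Cross-validated model assessment and VIP-threshold variable selection.

All cross-validation here is "full": every observation is held out exactly
once per N-fold split. Autoscaling parameters are always computed on the
training split only (no leakage); Q2 uses the full-sample response mean in
its denominator (SIMCA convention), switchable via ``q2_denominator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateModelError, FoldDegeneracyError, SelectionError
from .pls import PLSModel, fit_autoscaled_pls1, fit_stats, predict, vip
from .preprocess import autoscale



def kfold_split(n: int, N: int, seed: int) -> list[np.ndarray]:
    """Partition indices 0..n-1 into N random folds of near-equal size."""
    if not 2 <= N <= n:
        raise DegenerateModelError(f"need 2 <= N <= n; got N={N}, n={n}")
    rng = np.random.default_rng(seed)
    return [np.sort(fold) for fold in np.array_split(rng.permutation(n), N)]


@dataclass
class CVResult:
    """Out-of-fold prediction summary for one (A, N, seed) configuration."""

    q2: float
    rmsecv: float
    press: float
    oof_predictions: np.ndarray
    A: int
    N: int
    seed: int


def q2_cv(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    N: int,
    seed: int,
    *,
    q2_denominator: str = "full_mean",
    _leak_scaling: bool = False,
) -> CVResult:
    """N-fold full cross-validation of an A-component PLS1 model.

    For each fold the model (including autoscaling) is fitted on the
    training split only and the held-out rows are predicted on the percent
    scale. PRESS = sum (y - yhat_oof)^2, Q2 = 1 - PRESS / sum (y - ybar)^2,
    RMSECV = sqrt(PRESS / n).

    ``_leak_scaling`` deliberately computes scaling on the full data set;
    it exists only so audits can demonstrate the leakage guard matters.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    folds = kfold_split(n, N, seed)
    oof = np.empty(n)
    if _leak_scaling:
        Z_all, scaler = autoscale(X)
        y_mean, y_sd = float(y.mean()), float(y.std(ddof=1))
    for fold in folds:
        mask = np.ones(n, dtype=bool)
        mask[fold] = False
        y_train = y[mask]
        if np.ptp(y_train) == 0:
            raise FoldDegeneracyError(
                "a training split has zero response variance"
            )
        if _leak_scaling:
            from .pls import fit_pls1

            model = fit_pls1(
                Z_all[mask],
                (y_train - y_mean) / y_sd,
                A,
                x_scaler=scaler,
                y_mean=y_mean,
                y_sd=y_sd,
            )
            oof[fold] = predict(model, X[fold])
        else:
            model = fit_autoscaled_pls1(X[mask], y_train, A)
            oof[fold] = predict(model, X[fold])
    press = float(np.sum((y - oof) ** 2))
    if q2_denominator == "full_mean":
        tss = float(np.sum((y - y.mean()) ** 2))
    elif q2_denominator == "per_fold_mean":
        tss = 0.0
        for fold in folds:
            mask = np.ones(n, dtype=bool)
            mask[fold] = False
            tss += float(np.sum((y[fold] - y[mask].mean()) ** 2))
    else:
        raise ValueError(f"unknown q2_denominator {q2_denominator!r}")
    if tss == 0:
        raise DegenerateModelError("Q2 undefined: response has zero variance")
    return CVResult(
        q2=1.0 - press / tss,
        rmsecv=float(np.sqrt(press / n)),
        press=press,
        oof_predictions=oof,
        A=A,
        N=N,
        seed=seed,
    )


def _search_components(
    X: np.ndarray, y: np.ndarray, max_A: int, N: int, margin: float, seed: int
) -> tuple[int, CVResult]:
    if max_A < 1:
        raise DegenerateModelError("max_A must be >= 1")
    best = q2_cv(X, y, 1, N, seed)
    A = 1
    while A < max_A:
        try:
            nxt = q2_cv(X, y, A + 1, N, seed)
        except FoldDegeneracyError:
            raise
        except DegenerateModelError:
            break
        if nxt.q2 > best.q2 + margin:
            best, A = nxt, A + 1
        else:
            break
    return A, best


def select_components(
    X: np.ndarray,
    y: np.ndarray,
    max_A: int,
    N: int,
    margin: float = 0.01,
    seed: int = 0,
) -> int:
    """Choose the component count by forward Q2 improvement.

    Starts at A = 1 and increments while Q2_CV(N) improves by more than
    ``margin``; returns the last accepted A. An unfittable next component
    simply stops the search.
    """
    return _search_components(X, y, max_A, N, margin, seed)[0]


@dataclass
class SelectionResult:
    """Outcome of iterated VIP-threshold selection."""

    selected: np.ndarray  # column indices into the input matrix
    theta: float
    A: int
    q2: float
    rmsecv: float
    press: float
    model: PLSModel  # final model on the selected subset
    q2_full: float  # Q2 of the unselected model on the same folds
    n_iterations: int
    history: list[dict] = field(default_factory=list)


def vip_threshold_select(
    X: np.ndarray,
    y: np.ndarray,
    *,
    N: int = 7,
    max_A: int = 3,
    margin: float = 0.01,
    seed: int = 0,
    max_iter: int = 10,
) -> SelectionResult:
    """Select features by maximizing Q2 over VIP-score thresholds.

    Each round fits a model on the active features (A chosen by
    :func:`select_components`), computes VIPs, and evaluates every candidate
    threshold (the sorted unique VIP values) by refitting on the surviving
    subset with a re-selected A and scoring Q2 under the same fold scheme.
    The maximizing threshold wins; Q2 values within ``margin`` of the
    maximum count as ties, broken toward fewer features (parsimony, same
    margin as component selection). The procedure repeats on the winning
    subset until stable or ``max_iter`` rounds, then a greedy refinement
    alternates backward elimination (drop a feature while the best removal
    costs no more than ``margin`` of Q2) with single-feature forward steps
    (add a feature when it gains more than twice the margin). Thresholding
    only
    offers subsets nested in the VIP ranking, so without this pass a
    spuriously high-ranked feature could never be removed nor a low-ranked
    informative one recovered.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[1] < 1:
        raise SelectionError("no features to select from")
    active = np.arange(X.shape[1])
    cache: dict[tuple, tuple] = {}
    history: list[dict] = []
    q2_full = None

    def evaluate(subset: np.ndarray):
        key = tuple(subset.tolist())
        if key not in cache:
            cache[key] = _search_components(X[:, subset], y, max_A, N, margin, seed)
        return cache[key]

    theta_star = None
    final = None
    for iteration in range(max_iter):
        model = fit_autoscaled_pls1(
            X[:, active], y, evaluate(active)[0]
        )
        profile = vip(model)
        scores = profile.vip
        retained = scores > 0
        thetas = np.unique(scores[retained])
        candidates = []  # (q2, n_features, theta, subset, A, cv)
        for theta in thetas:
            subset = active[scores >= theta]
            try:
                A, cv = evaluate(subset)
            except DegenerateModelError:
                continue
            candidates.append((cv.q2, subset.size, float(theta), subset, A, cv))
        if not candidates:
            raise SelectionError("no VIP threshold yields a fittable model")
        q2_max = max(c[0] for c in candidates)
        # within-margin ties break toward fewer features, then higher theta
        best = min(
            (c for c in candidates if c[0] >= q2_max - margin),
            key=lambda c: (c[1], -c[2]),
        )
        if q2_full is None:
            full_A, full_cv = evaluate(active)
            q2_full = full_cv.q2
        history.append(
            {
                "iteration": iteration,
                "n_active": int(active.size),
                "theta": best[2],
                "n_selected": int(best[1]),
                "q2": best[0],
                "A": best[4],
            }
        )
        theta_star, final = best[2], best
        if np.array_equal(best[3], active):
            break
        active = best[3]
    q2_best, _, theta_star, subset, A, cv = final

    def _best_move(moves):
        scored = []
        for candidate in moves:
            try:
                A_c, cv_c = evaluate(candidate)
            except DegenerateModelError:
                continue
            scored.append((cv_c.q2, candidate, A_c, cv_c))
        return max(scored, key=lambda c: c[0]) if scored else None

    all_features = np.arange(X.shape[1])
    for _ in range(2 * X.shape[1]):
        moved = False
        if subset.size > 1:
            drop = _best_move(
                np.delete(subset, j) for j in range(subset.size)
            )
            if drop is not None and drop[0] >= q2_best - margin:
                q2_best, subset, A, cv = drop
                moved = True
                history.append(
                    {"move": "drop", "n_selected": int(subset.size), "q2": q2_best, "A": A}
                )
        if not moved:
            grow = _best_move(
                np.sort(np.append(subset, j))
                for j in np.setdiff1d(all_features, subset)
            )
            if grow is not None and grow[0] > q2_best + 2 * margin:
                q2_best, subset, A, cv = grow
                moved = True
                history.append(
                    {"move": "add", "n_selected": int(subset.size), "q2": q2_best, "A": A}
                )
        if not moved:
            break
    model = fit_autoscaled_pls1(X[:, subset], y, A)
    return SelectionResult(
        selected=subset,
        theta=theta_star,
        A=A,
        q2=q2_best,
        rmsecv=cv.rmsecv,
        press=cv.press,
        model=model,
        q2_full=float(q2_full),
        n_iterations=len(history),
        history=history,
    )


@dataclass
class PermutationResult:
    """Response-permutation null distributions and the empirical p-value."""

    r2_observed: float
    q2_observed: float
    r2_permuted: np.ndarray
    q2_permuted: np.ndarray
    p_value: float
    n_permutations: int


def permutation_test(
    X: np.ndarray,
    y: np.ndarray,
    A: int,
    n_perm: int,
    seed: int,
    *,
    N: int = 7,
) -> PermutationResult:
    """Refit under response permutation with the observed A and fold scheme.

    p = (1 + #{Q2_perm >= Q2_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise DegenerateModelError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    model = fit_autoscaled_pls1(X, y, A)
    r2_obs, _ = fit_stats(model, y)
    q2_obs = q2_cv(X, y, A, N, seed).q2
    rng = np.random.default_rng(seed)
    r2s = np.empty(n_perm)
    q2s = np.empty(n_perm)
    for b in range(n_perm):
        y_perm = y[rng.permutation(y.size)]
        perm_model = fit_autoscaled_pls1(X, y_perm, A)
        r2s[b], _ = fit_stats(perm_model, y_perm)
        q2s[b] = q2_cv(X, y_perm, A, N, seed).q2
    p = (1 + int(np.sum(q2s >= q2_obs))) / (1 + n_perm)
    return PermutationResult(
        r2_observed=r2_obs,
        q2_observed=q2_obs,
        r2_permuted=r2s,
        q2_permuted=q2s,
        p_value=p,
        n_permutations=n_perm,
    )
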