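"""Monte Carlo subsampling around the full VIP-selection procedure.

Repeated Bernoulli subsamples of the observations are each pushed through
the complete threshold-selection pipeline; the per-feature selection
frequency ("spectrum of most frequently used variables") stratifies the
metabolites into strong / weak / unrelated bands, and predictions on the
excluded observations give a pooled out-of-subsample RMSEP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateModelError, MetaboPLSError, StabilityError
from .pls import predict
from .tabular_io import RunConfig
from .validation import SelectionResult, vip_threshold_select

_MAX_REDRAW_FACTOR = 100  # rejection rate > 99% => infeasible


def mc_subsample(
    n: int,
    probability: float,
    n_samples: int,
    seed: int,
    *,
    min_size: int = 2,
    y: np.ndarray | None = None,
) -> tuple[list[np.ndarray], int]:
    """Draw Bernoulli(p) inclusion subsamples of 0..n-1, redrawing degenerates.

    A draw is rejected (and redrawn) if it has fewer than ``min_size``
    members or, when ``y`` is given, zero response variance over its
    members. Returns the subsamples and the number of rejected draws.
    """
    if not 0 < probability <= 1:
        raise DegenerateModelError("probability must lie in (0, 1]")
    if n_samples < 1 or n < 1:
        raise DegenerateModelError("n and n_samples must be positive")
    rng = np.random.default_rng(seed)
    subsamples: list[np.ndarray] = []
    rejected = 0
    budget = _MAX_REDRAW_FACTOR * n_samples
    while len(subsamples) < n_samples:
        if rejected > budget:
            raise StabilityError(
                f"subsampling infeasible: {rejected} rejected draws for "
                f"{len(subsamples)} accepted (n={n}, p={probability})"
            )
        idx = np.flatnonzero(rng.random(n) < probability)
        if idx.size < min_size:
            rejected += 1
            continue
        if y is not None and np.ptp(np.asarray(y)[idx]) == 0:
            rejected += 1
            continue
        subsamples.append(idx)
    return subsamples, rejected


@dataclass
class StabilityResult:
    """Selection-frequency spectrum and pooled out-of-subsample error."""

    frequencies: np.ndarray  # (p,) in [0, 1]
    classes: list[str]  # strong / weak / unrelated per feature
    directions: list[str]  # inverse / direct / none, from the full-data model
    rmsep: float  # pooled out-of-subsample RMSE, percent
    n_valid_subsamples: int
    n_failed_subsamples: int
    n_rejected_draws: int
    full_selection: SelectionResult


def classify_relevance(
    frequencies: np.ndarray,
    coefficient_signs: np.ndarray,
    strong_cutoff: float = 0.90,
    weak_cutoff: float = 0.50,
) -> tuple[list[str], list[str]]:
    """Band each feature by selection frequency and coefficient direction.

    Cutoffs are closed lower bounds: a frequency exactly at a cutoff joins
    the higher band. Direction is the sign of the feature's coefficient in
    the final full-data model (negative = inverse/protective).
    """
    if not weak_cutoff < strong_cutoff:
        raise DegenerateModelError("cutoffs must satisfy weak < strong")
    classes: list[str] = []
    directions: list[str] = []
    for freq, sign in zip(np.asarray(frequencies), np.asarray(coefficient_signs)):
        if freq >= strong_cutoff:
            classes.append("strong")
        elif freq >= weak_cutoff:
            classes.append("weak")
        else:
            classes.append("unrelated")
        directions.append("inverse" if sign < 0 else "direct" if sign > 0 else "none")
    return classes, directions


def mc_stability(
    X: np.ndarray,
    y: np.ndarray,
    config: RunConfig | None = None,
    *,
    full_selection: SelectionResult | None = None,
) -> StabilityResult:
    """Run VIP-threshold selection on Monte Carlo subsamples.

    Each subsample trains the complete selection procedure; its final model
    predicts the excluded observations, and those pooled squared errors give
    RMSEP. ``full_selection`` (the full-data selection) supplies coefficient
    signs for direction labels; it is computed here when not provided.
    """
    config = config or RunConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    min_size = config.n_folds_primary + 2
    subsamples, rejected = mc_subsample(
        n,
        config.mc_probability,
        config.mc_subsamples,
        config.seed,
        min_size=min_size,
        y=y,
    )
    if full_selection is None:
        full_selection = vip_threshold_select(
            X,
            y,
            N=config.n_folds_primary,
            max_A=config.max_components,
            margin=config.q2_gain_margin,
            seed=config.seed,
        )
    counts = np.zeros(p)
    sq_errors: list[np.ndarray] = []
    n_valid = 0
    n_failed = 0
    for offset, idx in enumerate(subsamples):
        # per-subsample offset keeps the whole analysis replayable bit-identically
        sub_seed = config.seed + 1 + offset
        try:
            sel = vip_threshold_select(
                X[idx],
                y[idx],
                N=config.n_folds_primary,
                max_A=config.max_components,
                margin=config.q2_gain_margin,
                seed=sub_seed,
            )
        except MetaboPLSError:
            n_failed += 1
            continue
        n_valid += 1
        counts[sel.selected] += 1
        excluded = np.setdiff1d(np.arange(n), idx)
        if excluded.size:
            y_hat = predict(sel.model, X[np.ix_(excluded, sel.selected)])
            sq_errors.append((y[excluded] - y_hat) ** 2)
    if n_valid == 0:
        raise StabilityError("all Monte Carlo subsamples failed selection")
    frequencies = counts / n_valid
    signs = np.zeros(p)
    coef = full_selection.model.coef
    keep = full_selection.model.x_scaler.keep
    signs[full_selection.selected[keep]] = np.sign(coef)
    classes, directions = classify_relevance(
        frequencies,
        signs,
        config.strong_freq_cutoff,
        config.weak_freq_cutoff,
    )
    pooled = np.concatenate(sq_errors) if sq_errors else np.array([np.nan])
    return StabilityResult(
        frequencies=frequencies,
        classes=classes,
        directions=directions,
        rmsep=float(np.sqrt(np.mean(pooled))),
        n_valid_subsamples=n_valid,
        n_failed_subsamples=n_failed,
        n_rejected_draws=rejected,
        full_selection=full_selection,
    )
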