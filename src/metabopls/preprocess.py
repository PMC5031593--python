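"""Scaling, damage normalization, metabolite grouping, and post-stress screens."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import DegenerateModelError, SchemaError, TableValidationError
from .tabular_io import FeatureTable


@dataclass
class ScalingParams:
    """Per-feature autoscaling parameters (mean, SD with denominator n - 1).

    Zero-variance columns are dropped from the scaled output; their input
    indices are recorded in ``dropped``.
    """

    mean: np.ndarray
    sd: np.ndarray
    keep: np.ndarray  # indices of retained columns in the input matrix
    dropped: np.ndarray  # indices of zero-variance columns
    n_input_features: int

    def transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X.reshape(1, -1)
        if X.shape[1] != self.n_input_features:
            raise SchemaError(
                f"expected {self.n_input_features} features, got {X.shape[1]}"
            )
        return (X[:, self.keep] - self.mean) / self.sd


def autoscale(X: np.ndarray) -> tuple[np.ndarray, ScalingParams]:
    """Center each column to mean 0 and scale to unit sample SD.

    Columns with zero variance cannot be scaled; they are dropped and listed
    in the returned params so the identical transform applies to new rows.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise DegenerateModelError("autoscaling needs a matrix with >= 2 rows")
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    dropped = np.flatnonzero(sd == 0)
    if keep.size == 0:
        raise DegenerateModelError("no informative features: all columns constant")
    params = ScalingParams(
        mean=mean[keep],
        sd=sd[keep],
        keep=keep,
        dropped=dropped,
        n_input_features=X.shape[1],
    )
    return params.transform(X), params


@dataclass
class CountSummary:
    """A scored-event proportion from raw cell counts."""

    n_event: int
    n_total: int
    proportion_pct: float


def proportion_from_counts(n_event: int, n_total: int) -> CountSummary:
    """Percentage of counted cells showing the scored outcome, to one decimal."""
    if n_total <= 0:
        raise DegenerateModelError("n_total must be positive")
    if not 0 <= n_event <= n_total:
        raise TableValidationError(
            f"n_event must lie in [0, n_total]; got {n_event}/{n_total}"
        )
    return CountSummary(
        n_event=int(n_event),
        n_total=int(n_total),
        proportion_pct=round(100.0 * n_event / n_total, 1),
    )


def relative_damage(treated_pct: float, control_pct: float) -> float:
    """Treated damage as a percentage of the paired control's damage.

    Values below 100 indicate protection; above 100 indicate sensitization.
    """
    for name, v in (("treated_pct", treated_pct), ("control_pct", control_pct)):
        if not 0 <= v <= 100:
            raise TableValidationError(f"{name}={v} outside [0, 100]")
    if control_pct == 0:
        raise DegenerateModelError(
            "control damage is 0%; relative damage is undefined"
        )
    return 100.0 * treated_pct / control_pct


def paired_effect_test(
    control_pcts, treated_pcts, method: str = "t"
) -> tuple[float, float]:
    """Two-sided paired test on (treated - control) damage percentages."""
    control = np.asarray(control_pcts, dtype=float)
    treated = np.asarray(treated_pcts, dtype=float)
    if control.shape != treated.shape or control.ndim != 1 or control.size < 2:
        raise TableValidationError("need equal-length paired lists with >= 2 pairs")
    diffs = treated - control
    if method == "t":
        if np.ptp(diffs) == 0:
            if diffs[0] == 0:
                return 0.0, 1.0
            raise DegenerateModelError(
                "all paired differences identical and non-zero: "
                "t statistic undefined (zero variance)"
            )
        res = stats.ttest_rel(treated, control)
        return float(res.statistic), float(res.pvalue)
    if method == "wilcoxon":
        if np.all(diffs == 0):
            raise DegenerateModelError(
                "all paired differences zero: Wilcoxon test degenerate"
            )
        res = stats.wilcoxon(treated, control)
        return float(res.statistic), float(res.pvalue)
    raise TableValidationError(f"unknown method {method!r}; expected 't' or 'wilcoxon'")


def group_metabolites(
    table: FeatureTable, groups: dict[str, list[str]]
) -> FeatureTable:
    """Sum member features into named group features.

    Each group becomes one column equal to the sum of its members; features
    not named in any group pass through unchanged, in their original order.
    Groups may overlap (a member can contribute to several groups).
    """
    index = {mid: j for j, mid in enumerate(table.metabolite_ids)}
    grouped_members: set[str] = set()
    new_ids: list[str] = []
    columns: list[np.ndarray] = []
    for gid, members in groups.items():
        if not members:
            raise SchemaError(f"group {gid!r} has no members")
        unknown = [m for m in members if m not in index]
        if unknown:
            raise SchemaError(f"group {gid!r} names unknown metabolites {unknown}")
        cols = [index[m] for m in members]
        new_ids.append(gid)
        columns.append(table.abundances[:, cols].sum(axis=1))
        grouped_members.update(members)
    for mid in table.metabolite_ids:
        if mid not in grouped_members:
            new_ids.append(mid)
            columns.append(table.abundances[:, index[mid]])
    abundances = (
        np.column_stack(columns) if columns else np.empty((table.n_samples, 0))
    )
    return FeatureTable(
        sample_ids=list(table.sample_ids),
        metabolite_ids=new_ids,
        abundances=abundances,
        session_ids=list(table.session_ids),
        treatments=list(table.treatments),
        damage_pct=table.damage_pct.copy(),
    )


@dataclass
class ScreenResult:
    """Per-feature fold changes after stress, plus the total-signal shift."""

    metabolite_ids: list[str]
    fold_change: np.ndarray
    flagged: np.ndarray  # boolean, fold_change >= min_fold
    min_fold: float
    floor: float
    total_signal_change_pct: float
    flagged_ids: list[str] = field(init=False)

    def __post_init__(self) -> None:
        self.flagged_ids = [
            m for m, f in zip(self.metabolite_ids, self.flagged) if f
        ]


def fold_change_screen(
    pre_table: FeatureTable,
    post_table: FeatureTable,
    min_fold: float = 2.0,
    floor: float | None = None,
) -> ScreenResult:
    """Screen for features accumulating >= min_fold after stress.

    Fold change is mean(post) / max(mean(pre), floor); the detection floor
    (default 1% of the median pre-stress feature mean) keeps barely
    detectable baselines from producing unbounded ratios. The total-signal
    change is 100 * (sum(post) - sum(pre)) / sum(pre).
    """
    if pre_table.metabolite_ids != post_table.metabolite_ids:
        raise SchemaError("pre and post tables must share the same metabolite set")
    if min_fold <= 1:
        raise TableValidationError("min_fold must exceed 1")
    pre_mean = pre_table.abundances.mean(axis=0)
    post_mean = post_table.abundances.mean(axis=0)
    if floor is None:
        med = float(np.median(pre_mean)) if pre_mean.size else 0.0
        floor = 0.01 * med if med > 0 else 1e-12
    if floor <= 0:
        raise TableValidationError("floor must be positive")
    fold = post_mean / np.maximum(pre_mean, floor)
    pre_total = float(pre_table.abundances.sum())
    post_total = float(post_table.abundances.sum())
    if pre_total <= 0:
        raise DegenerateModelError("pre-stress total signal is zero")
    return ScreenResult(
        metabolite_ids=list(pre_table.metabolite_ids),
        fold_change=fold,
        flagged=fold >= min_fold,
        min_fold=float(min_fold),
        floor=float(floor),
        total_signal_change_pct=100.0 * (post_total - pre_total) / pre_total,
    )
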