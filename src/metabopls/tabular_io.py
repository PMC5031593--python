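"""Feature-table I/O, validation, run configuration, and JSON reporting.

The on-disk layout is a flat CSV/TSV with four reserved metadata columns
(``sample_id``, ``session_id``, ``treatment``, ``damage_pct``); every other
column is a metabolite feature. Abundances are non-negative relative
intensities; the response is a percentage in [0, 100].
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigError,
    ReportError,
    SchemaError,
    TableParseError,
    TableValidationError,
)

RESERVED_COLUMNS = ("sample_id", "session_id", "treatment", "damage_pct")
TREATMENTS = ("control", "coumaric", "ferulic", "sinapic", "caffeic", "pip")
FED_TREATMENTS = ("coumaric", "ferulic", "sinapic", "caffeic", "pip")

_DELIMITERS = {"csv": ",", "tsv": "\t"}


@dataclass
class FeatureTable:
    """Samples x metabolites abundance matrix with metadata and response.

    Attributes
    ----------
    sample_ids : list of str
        Unique sample identifiers, one per row of ``abundances``.
    metabolite_ids : list of str
        Unique feature identifiers, one per column.
    abundances : ndarray of shape (n_samples, n_metabolites)
        Non-negative relative intensities.
    session_ids : list of str
        Experimental session label per sample.
    treatments : list of str
        One of ``TREATMENTS`` per sample.
    damage_pct : ndarray of shape (n_samples,)
        Percentage of FDA-positive cells with cytoplasmic patches, in [0, 100].
    """

    sample_ids: list[str]
    metabolite_ids: list[str]
    abundances: np.ndarray
    session_ids: list[str]
    treatments: list[str]
    damage_pct: np.ndarray

    def __post_init__(self) -> None:
        self.abundances = np.asarray(self.abundances, dtype=float)
        if self.abundances.ndim == 1:
            self.abundances = self.abundances.reshape(len(self.sample_ids), -1)
        self.damage_pct = np.asarray(self.damage_pct, dtype=float)
        self.validate()

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_features(self) -> int:
        return len(self.metabolite_ids)

    def validate(self) -> None:
        n, p = len(self.sample_ids), len(self.metabolite_ids)
        if self.abundances.shape != (n, p):
            raise TableValidationError(
                f"abundance matrix shape {self.abundances.shape} does not match "
                f"{n} samples x {p} metabolites"
            )
        if len(set(self.sample_ids)) != n:
            raise TableValidationError("duplicate sample identifiers")
        if len(set(self.metabolite_ids)) != p:
            raise TableValidationError("duplicate metabolite identifiers")
        for reserved in RESERVED_COLUMNS:
            if reserved in self.metabolite_ids:
                raise TableValidationError(
                    f"metabolite id collides with reserved column {reserved!r}"
                )
        if len(self.session_ids) != n or len(self.treatments) != n:
            raise TableValidationError("metadata length does not match sample count")
        if any(s is None or str(s) == "" for s in self.session_ids):
            raise TableValidationError("every sample needs a session_id")
        bad = [t for t in self.treatments if t not in TREATMENTS]
        if bad:
            raise TableValidationError(
                f"unknown treatment(s) {sorted(set(bad))}; expected one of {TREATMENTS}"
            )
        if self.damage_pct.shape != (n,):
            raise TableValidationError("damage_pct length does not match sample count")
        if np.any(~np.isfinite(self.damage_pct)):
            raise TableValidationError("damage_pct contains non-finite values")
        if np.any((self.damage_pct < 0) | (self.damage_pct > 100)):
            raise TableValidationError(
                "damage_pct outside the valid range [0, 100]"
            )
        if np.any(~np.isfinite(self.abundances)):
            raise TableValidationError(
                "abundance matrix contains missing or non-finite cells"
            )
        if np.any(self.abundances < 0):
            raise TableValidationError("abundances must be non-negative")

    def subset(self, rows: Sequence[int]) -> "FeatureTable":
        rows = list(rows)
        return FeatureTable(
            sample_ids=[self.sample_ids[i] for i in rows],
            metabolite_ids=list(self.metabolite_ids),
            abundances=self.abundances[rows],
            session_ids=[self.session_ids[i] for i in rows],
            treatments=[self.treatments[i] for i in rows],
            damage_pct=self.damage_pct[rows],
        )

    def equals(self, other: "FeatureTable") -> bool:
        return (
            self.sample_ids == other.sample_ids
            and self.metabolite_ids == other.metabolite_ids
            and self.session_ids == other.session_ids
            and self.treatments == other.treatments
            and np.array_equal(self.abundances, other.abundances)
            and np.array_equal(self.damage_pct, other.damage_pct)
        )

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            {
                "sample_id": self.sample_ids,
                "session_id": self.session_ids,
                "treatment": self.treatments,
                "damage_pct": self.damage_pct,
            }
        )
        for j, mid in enumerate(self.metabolite_ids):
            frame[mid] = self.abundances[:, j]
        return frame


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _DELIMITERS:
            raise ConfigError(f"unknown table format {fmt!r}; expected csv or tsv")
        return fmt
    return "tsv" if path.suffix.lower() in (".tsv", ".tab") else "csv"


def read_feature_table(path: str | Path, format: str | None = None) -> FeatureTable:
    """Read and validate a feature table from CSV or TSV.

    Raises
    ------
    SchemaError
        If a reserved metadata column is absent.
    TableParseError
        If an abundance or response cell is not numeric; the message names
        the offending sample row and column.
    TableValidationError
        If the parsed table violates a FeatureTable invariant.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    frame = pd.read_csv(path, sep=_DELIMITERS[fmt], dtype=str, keep_default_na=False)
    for reserved in RESERVED_COLUMNS:
        if reserved not in frame.columns:
            raise SchemaError(f"missing reserved column {reserved!r}")
    metabolite_ids = [c for c in frame.columns if c not in RESERVED_COLUMNS]

    def _numeric(column: str) -> np.ndarray:
        raw = frame[column].to_numpy()
        try:
            # exact parse; pd.to_numeric would round-trip doubles lossily
            values = frame[column].astype(float).to_numpy()
        except ValueError:
            values = None
        empty = np.flatnonzero(raw == "")
        if values is None or empty.size:
            for i, cell in enumerate(raw):
                try:
                    if cell == "":
                        raise ValueError
                    float(cell)
                except ValueError:
                    raise TableParseError(
                        f"non-numeric value {cell!r} in column {column!r}, "
                        f"row {i + 2} (sample {frame['sample_id'].iloc[i]!r})"
                    ) from None
        return values

    damage = _numeric("damage_pct")
    if metabolite_ids:
        abundances = np.column_stack([_numeric(m) for m in metabolite_ids])
    else:
        abundances = np.empty((len(frame), 0))
    return FeatureTable(
        sample_ids=frame["sample_id"].tolist(),
        metabolite_ids=metabolite_ids,
        abundances=abundances,
        session_ids=frame["session_id"].tolist(),
        treatments=frame["treatment"].tolist(),
        damage_pct=damage,
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, format: str | None = None
) -> None:
    """Write a feature table such that :func:`read_feature_table` round-trips it.

    Floats are serialised with Python's shortest round-trip repr, so every
    double survives write-then-read bit-exactly.
    """
    path = Path(path)
    fmt = _infer_format(path, format)
    table.validate()
    # shortest round-trip repr keeps every double bit-exact through the file
    table.to_frame().to_csv(
        path, sep=_DELIMITERS[fmt], index=False, float_format=lambda v: repr(float(v))
    )


REQUIRED_MODEL_KEYS = ("selected", "A", "R2", "Q2", "errors", "permutation")


def write_report(results: Mapping[str, object], path: str | Path) -> None:
    """Emit the assembled analysis report as JSON.

    ``results["models"]`` maps model names (e.g. ``controls``, ``fed``,
    ``all``) to summary blocks. Each block must either carry the full key
    set ``REQUIRED_MODEL_KEYS`` or be an explicit no-model record
    (``{"no_model": true, "reason": ...}``).
    """
    models = results.get("models")
    if not models:
        raise ReportError("results contain no fitted model blocks")
    missing: list[str] = []
    for name, block in models.items():
        if isinstance(block, Mapping) and block.get("no_model"):
            continue
        for key in REQUIRED_MODEL_KEYS:
            if key not in block:
                missing.append(f"{name}.{key}")
    if missing:
        raise ReportError("incomplete report; missing sections: " + ", ".join(missing))
    Path(path).write_text(json.dumps(_jsonable(results), indent=2, sort_keys=True))


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    return obj


@dataclass
class RunConfig:
    """Knobs of the full analysis, mirroring the study's settings."""

    n_folds_primary: int = 7
    n_folds_robustness: list[int] = field(default_factory=lambda: [6, 7, 8])
    n_permutations: int = 1000
    mc_subsamples: int = 100
    mc_probability: float = 0.70
    max_components: int = 3
    q2_gain_margin: float = 0.01
    outlier_alpha: float = 0.01
    seed: int = 0
    strong_freq_cutoff: float = 0.90
    weak_freq_cutoff: float = 0.50
    exclude_caffeic: bool = True

    def __post_init__(self) -> None:
        counts = {
            "n_folds_primary": self.n_folds_primary,
            "n_permutations": self.n_permutations,
            "mc_subsamples": self.mc_subsamples,
            "max_components": self.max_components,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        if not self.n_folds_robustness or any(
            int(v) != v or v < 2 for v in self.n_folds_robustness
        ):
            raise ConfigError("n_folds_robustness must list integers >= 2")
        if not 0 < self.mc_probability <= 1:
            raise ConfigError("mc_probability must lie in (0, 1]")
        if not 0 < self.outlier_alpha < 1:
            raise ConfigError("outlier_alpha must lie in (0, 1)")
        if not 0 < self.weak_freq_cutoff < self.strong_freq_cutoff <= 1:
            raise ConfigError(
                "frequency cutoffs must satisfy 0 < weak < strong <= 1"
            )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)
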