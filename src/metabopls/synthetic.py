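"""Synthetic feature tables with session structure, feeding boosts, and a
planted protective metabolite set.

The generative model is log-normal on the abundance side:

    log x_ij = mu_j + s_{k(i), j} + log(boost) * 1[treatment(i) targets j] + eps_ij

with per-session-per-feature offsets s ~ N(0, session_sd_metabolome^2) and
measurement noise eps ~ N(0, noise_sd_metabolome^2). The damage response is
linear in the *autoscaled* abundances of the protective features:

    damage_i = baseline + gamma_{k(i)} + sum_j beta_j z_ij + e_i,

clipped to [0, 100]. Each experiment contributes two same-session samples:
an unfed control and a fed sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .tabular_io import FED_TREATMENTS, FeatureTable


def _default_experiments() -> dict[str, int]:
    return {"coumaric": 6, "ferulic": 4, "sinapic": 4}


def _default_target_map() -> dict[str, list[int]]:
    return {"coumaric": [0, 3], "ferulic": [1, 4], "sinapic": [2, 5]}


@dataclass
class SyntheticSpec:
    """Parameters of the generator; defaults mirror the study's design shape."""

    n_sessions: int = 8
    experiments_per_treatment: dict[str, int] = field(
        default_factory=_default_experiments
    )
    p_features: int = 50
    protective_set: list[int] = field(default_factory=lambda: [0, 1, 2])
    protective_coefficients: list[float] = field(
        default_factory=lambda: [-8.0, -8.0, -8.0]
    )
    target_map: dict[str, list[int]] = field(default_factory=_default_target_map)
    boost_factor: float = 4.0
    pip_factor: float = 0.5  # multiplicative suppression of protective features
    session_sd_metabolome: float = 0.5  # log scale
    session_sd_response: float = 1.0  # percent
    baseline_damage: float = 60.0
    noise_sd_metabolome: float = 0.3  # log scale
    noise_sd_response: float = 1.0  # percent
    seed: int = 0

    def validate(self) -> None:
        if self.n_sessions < 1 or self.p_features < 1:
            raise ConfigError("n_sessions and p_features must be positive")
        if not self.experiments_per_treatment:
            raise ConfigError("experiments_per_treatment must not be empty")
        for tr, count in self.experiments_per_treatment.items():
            if tr not in FED_TREATMENTS:
                raise ConfigError(f"unknown fed treatment {tr!r}")
            if count < 1:
                raise ConfigError(f"experiment count for {tr!r} must be positive")
        if len(self.protective_set) != len(self.protective_coefficients):
            raise ConfigError(
                "protective_set and protective_coefficients lengths differ"
            )
        if any(not 0 <= j < self.p_features for j in self.protective_set):
            raise ConfigError("protective_set indices outside the feature range")
        for tr, targets in self.target_map.items():
            if not targets:
                raise ConfigError(f"treatment {tr!r} has no target features")
            if any(not 0 <= j < self.p_features for j in targets):
                raise ConfigError(f"target indices for {tr!r} outside feature range")
        if self.boost_factor <= 0 or self.pip_factor <= 0:
            raise ConfigError("boost_factor and pip_factor must be positive")
        if not 0 < self.baseline_damage < 100:
            raise ConfigError("baseline_damage must lie in (0, 100)")
        for name in (
            "session_sd_metabolome",
            "session_sd_response",
            "noise_sd_metabolome",
            "noise_sd_response",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")


@dataclass
class GroundTruth:
    """The generator's planted structure, for recovery tests."""

    protective_set: list[int]
    protective_coefficients: np.ndarray  # (p,), zero off the planted set
    session_metabolome_offsets: np.ndarray  # (n_sessions, p), log scale
    session_response_offsets: np.ndarray  # (n_sessions,), percent
    noiseless_response: np.ndarray  # (n,), pre-noise, pre-clipping
    n_clipped: int


def generate_dataset(spec: SyntheticSpec) -> tuple[FeatureTable, GroundTruth]:
    """Draw one feature table plus its ground truth from the generative model."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    p = spec.p_features

    sessions: list[str] = []
    treatments: list[str] = []
    sample_ids: list[str] = []
    session_idx: list[int] = []
    exp = 0
    for tr in sorted(spec.experiments_per_treatment):
        for _ in range(spec.experiments_per_treatment[tr]):
            k = exp % spec.n_sessions
            for arm in ("control", tr):
                sample_ids.append(f"exp{exp + 1:02d}_{arm}")
                sessions.append(f"session{k + 1}")
                treatments.append(arm)
                session_idx.append(k)
            exp += 1
    n = len(sample_ids)
    session_idx = np.asarray(session_idx)

    mu = rng.normal(np.log(100.0), 0.5, size=p)
    s = rng.normal(0.0, spec.session_sd_metabolome, size=(spec.n_sessions, p))
    gamma = rng.normal(0.0, spec.session_sd_response, size=spec.n_sessions)
    eps = rng.normal(0.0, spec.noise_sd_metabolome, size=(n, p))
    e = rng.normal(0.0, spec.noise_sd_response, size=n)

    log_x = mu + s[session_idx] + eps
    for i, tr in enumerate(treatments):
        if tr in spec.target_map:
            log_x[i, spec.target_map[tr]] += np.log(spec.boost_factor)
        if tr == "pip":
            log_x[i, spec.protective_set] += np.log(spec.pip_factor)
    abundances = np.exp(log_x)

    beta = np.zeros(p)
    beta[spec.protective_set] = spec.protective_coefficients
    sd = abundances.std(axis=0, ddof=1)
    safe_sd = np.where(sd > 0, sd, 1.0)
    z = (abundances - abundances.mean(axis=0)) / safe_sd
    z[:, sd == 0] = 0.0

    noiseless = spec.baseline_damage + gamma[session_idx] + z @ beta
    damage = noiseless + e
    clipped = np.clip(damage, 0.0, 100.0)
    n_clipped = int(np.sum(clipped != damage))

    table = FeatureTable(
        sample_ids=sample_ids,
        metabolite_ids=[f"met{j + 1:03d}" for j in range(p)],
        abundances=abundances,
        session_ids=sessions,
        treatments=treatments,
        damage_pct=clipped,
    )
    truth = GroundTruth(
        protective_set=list(spec.protective_set),
        protective_coefficients=beta,
        session_metabolome_offsets=s,
        session_response_offsets=gamma,
        noiseless_response=noiseless,
        n_clipped=n_clipped,
    )
    return table, truth


_FIXTURE_METABOLITES = [
    "coumaric acid h.2",
    "ferulic acid h.",
    "Cy(caf)tot",
    "coumaric aspartic acid-1",
    "dicaffeic daucic acid",
    "sinapic acid h.",
]

_FIXTURE_ABUNDANCES = [
    [120.0, 80.0, 35.0, 10.0, 5.0, 22.0],
    [310.0, 95.0, 60.0, 42.0, 6.0, 25.0],
    [100.0, 70.0, 30.0, 12.0, 7.5, 20.0],
    [280.0, 88.0, 55.0, 38.0, 8.0, 24.0],
    [140.0, 92.0, 40.0, 14.0, 4.5, 26.0],
    [350.0, 105.0, 70.0, 48.0, 5.5, 28.0],
    [90.0, 65.0, 28.0, 9.0, 6.5, 18.0],
    [260.0, 82.0, 50.0, 35.0, 7.0, 21.0],
]

_FIXTURE_DAMAGE = [62.0, 38.0, 70.0, 42.0, 55.0, 30.0, 74.0, 46.0]


def generate_worked_fixture() -> FeatureTable:
    """A fixed, seed-independent 8-sample x 6-metabolite regression fixture.

    Four sessions, each contributing a paired control and coumaric-fed
    sample; damage falls with the hydroxycinnamic-derivative abundances.
    The values are hand-specified literals so downstream expected results
    can be frozen once and asserted forever.
    """
    return FeatureTable(
        sample_ids=[f"fx{i + 1}_{arm}" for i in range(4) for arm in ("ctrl", "fed")],
        metabolite_ids=list(_FIXTURE_METABOLITES),
        abundances=np.array(_FIXTURE_ABUNDANCES),
        session_ids=[f"session{i + 1}" for i in range(4) for _ in range(2)],
        treatments=["control", "coumaric"] * 4,
        damage_pct=np.array(_FIXTURE_DAMAGE),
    )
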