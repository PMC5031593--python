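import numpy as np
import pytest

from metabopls.synthetic import SyntheticSpec, generate_dataset, generate_worked_fixture
from metabopls.tabular_io import FeatureTable


@pytest.fixture
def fixture_table():
    return generate_worked_fixture()


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def acceptance_spec(seed: int) -> SyntheticSpec:
    """The study-shaped generator config: 16 fed + 16 paired control samples,
    p = 50, 3 planted protective features, session-dominant metabolome."""
    return SyntheticSpec(
        seed=seed,
        experiments_per_treatment={"coumaric": 6, "ferulic": 5, "sinapic": 5},
        target_map={"coumaric": [0], "ferulic": [1], "sinapic": [2]},
    )


@pytest.fixture
def synth_pair():
    return generate_dataset(acceptance_spec(0))


def random_table(rng: np.random.Generator, n: int = 10, p: int = 6) -> FeatureTable:
    treatments = ["control", "coumaric", "ferulic", "sinapic", "caffeic", "pip"]
    return FeatureTable(
        sample_ids=[f"s{i}" for i in range(n)],
        metabolite_ids=[f"m{j}" for j in range(p)],
        abundances=rng.gamma(2.0, 50.0, size=(n, p)),
        session_ids=[f"sess{i % 3}" for i in range(n)],
        treatments=[treatments[i % len(treatments)] for i in range(n)],
        damage_pct=rng.uniform(0, 100, size=n),
    )
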