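import numpy as np
import pytest

import owlfid as o


@pytest.fixture(scope="session")
def default_dataset() -> o.SyntheticDataset:
    """One default-design synthetic population shared across tests."""
    return o.simulate_dataset(o.SimulationConfig(seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def founders(n: int, sex_cycle=("female", "male"), habitat="rural"):
    return [
        o.Individual(id=f"F{k}", sex=sex_cycle[k % len(sex_cycle)], habitat=habitat)
        for k in range(n)
    ]


@pytest.fixture()
def fullsib_mating_pedigree() -> o.Pedigree:
    """Founders A, B; full sibs C, D; E their offspring (F_E = 0.25)."""
    return o.validate_pedigree(
        [
            o.Individual(id="A", sex="male"),
            o.Individual(id="B", sex="female"),
            o.Individual(id="C", sire="A", dam="B", sex="male"),
            o.Individual(id="D", sire="A", dam="B", sex="female"),
            o.Individual(id="E", sire="C", dam="D"),
        ]
    )
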