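import numpy as np
import pytest

from pedeval.pedigree import PedigreeTable, topological_sort
from pedeval.simulate import FactorConfig, SimulationConfig, simulate_records


@pytest.fixture
def trio_pedigree():
    """Sire, dam, offspring."""
    return topological_sort(PedigreeTable.from_entries(
        [("S", "0", "0"), ("D", "0", "0"), ("X", "S", "D")]))


@pytest.fixture
def fullsib_pedigree():
    """Two founders, two full sibs, one inbred offspring of the sibs."""
    return topological_sort(PedigreeTable.from_entries([
        ("S", "0", "0"), ("D", "0", "0"),
        ("A", "S", "D"), ("B", "S", "D"), ("Z", "A", "B"),
    ]))


def random_pedigree(rng, n_founders=10, n_extra=40):
    """Random multi-generation pedigree with inbreeding loops."""
    entries = [(f"F{i}", "0", "0") for i in range(n_founders)]
    ids = [e[0] for e in entries]
    for k in range(n_extra):
        s, d = rng.choice(len(ids), size=2, replace=False)
        entries.append((f"X{k}", ids[s], ids[d]))
        ids.append(f"X{k}")
    return topological_sort(PedigreeTable.from_entries(entries))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def small_sim_config(seed=7, **overrides):
    """A compact herdbook the tests can fit quickly."""
    defaults = dict(
        n_founders=30, n_generations=2, n_offspring=60, n_herds=3,
        years=(2000, 2004), seed=seed,
        records_per_cow=(0.4, 0.3, 0.2, 0.1),
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def no_fixed_effects():
    return {"season": FactorConfig(2, 0.0), "evaluator": FactorConfig(0, 0.0),
            "diet": FactorConfig(3, 0.0)}


@pytest.fixture
def small_dataset():
    return simulate_records(config=small_sim_config())
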