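import numpy as np
import pandas as pd
import pytest

import diseasemap as dm


@pytest.fixture(scope="session")
def lattice_4x5():
    return dm.make_lattice(4, 5)


@pytest.fixture(scope="session")
def lattice_10x10():
    return dm.make_lattice(10, 10)


@pytest.fixture(scope="session")
def path_graph():
    """A-B-C-D path graph."""
    return dm.build_adjacency([("A", "B"), ("B", "C"), ("C", "D")], ["A", "B", "C", "D"])


@pytest.fixture(scope="session")
def small_registry():
    """One small synthetic registry shared by read-only tests."""
    scenario = dm.SimulationScenario(nrows=5, ncols=6, n_periods=3, seed=42,
                                     total_population=400_000.0)
    return dm.simulate_registry(scenario)


def random_graph(rng, n_max=150):
    """Random connected-ish graph for oracle comparisons."""
    n = int(rng.integers(4, n_max + 1))
    ids = list(range(n))
    edges = set()
    # random spanning structure plus extra edges; some graphs stay disconnected
    m = int(rng.integers(n // 2, 2 * n))
    while len(edges) < m:
        a, b = rng.integers(0, n, size=2)
        if a != b:
            edges.add((min(a, b), max(a, b)))
    return dm.build_adjacency(sorted(edges), ids)


def toy_cases(rows):
    """Build a case DataFrame from (region, sex, age_group, year, topography) tuples."""
    return pd.DataFrame(rows, columns=["region_id", "sex", "age_group", "year", "topography"])


def toy_pops(rows):
    return pd.DataFrame(rows, columns=["region_id", "sex", "age_group", "count"])
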