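import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from attrical.simulate import SimulationConfig, simulate_panel


def small_config(**overrides) -> SimulationConfig:
    """A fast panel configuration for unit tests."""
    base = dict(n_users=300, mean_out_degree=8.0, seed=7)
    base.update(overrides)
    return SimulationConfig(**base)


@pytest.fixture(scope="session")
def small_panel():
    """One simulated community shared across read-only tests."""
    return simulate_panel(small_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(123)


def random_digraph(rng, n=50, p=0.08):
    """Random simple directed graph as (nodes, edge list)."""
    mask = rng.uniform(size=(n, n)) < p
    np.fill_diagonal(mask, False)
    edges = [(int(i), int(j)) for i, j in zip(*np.nonzero(mask))]
    return list(range(n)), edges


def peel_in_coreness(nodes, edges):
    """Brute-force in-coreness by iterative peeling, independent of igraph.

    For each k, repeatedly delete nodes with in-degree < k inside the
    surviving subgraph; survivors have in-coreness >= k.
    """
    core = {v: 0 for v in nodes}
    alive = set(nodes)
    k = 1
    while alive:
        # peel at level k
        current = set(alive)
        changed = True
        while changed:
            changed = False
            indeg = {v: 0 for v in current}
            for a, b in edges:
                if a in current and b in current:
                    indeg[b] += 1
            drop = {v for v in current if indeg[v] < k}
            if drop:
                current -= drop
                changed = True
        for v in current:
            core[v] = k
        alive = current
        k += 1
    return core
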