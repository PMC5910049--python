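"""Shared fixtures: catalogs and cached toy/full-scale runs.

Simulation fixtures are session-scoped because several tests read different
statistics off the same trajectories; every run is fully determined by its
seed, so caching does not couple tests.
"""

from __future__ import annotations

import pytest

from gardpop import generate_default_catalog, make_toy_catalog, run
from gardpop.simulate import SimulationConfig, toy_config


@pytest.fixture(scope="session")
def default_catalog():
    return generate_default_catalog()


@pytest.fixture(scope="session")
def toy_catalog():
    """10-species catalog: two per class plus CHOL's single species."""
    return make_toy_catalog(n_per_class=2)


def _steady_state_runs(mode, seeds, catalog):
    """Toy runs continued past pool depletion to the compositional steady
    state (stop on time, not generation)."""
    return [
        run(toy_config(mode, rng_seed=s, stop_generation=1e9, t_max=60.0), catalog)
        for s in seeds
    ]


@pytest.fixture(scope="session")
def steady_full_runs(default_catalog):
    return _steady_state_runs("full", (11, 12, 13), default_catalog)


@pytest.fixture(scope="session")
def steady_invariant_runs(default_catalog):
    return _steady_state_runs("invariant", (11, 12, 13), default_catalog)


@pytest.fixture(scope="session")
def full_scale_run(default_catalog):
    """One default-configuration full-kinetics run at the complete budget
    (4.096e7 molecules, division at 20,000, stop at mean generation 12)."""
    return run(SimulationConfig(mode="full", rng_seed=2026), default_catalog)
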