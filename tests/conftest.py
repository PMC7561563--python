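import numpy as np
import pandas as pd
import pytest

from saprosucc import SimulationParams, simulate_study, filter_aspen_associated


@pytest.fixture(scope="session")
def demo_study():
    """One aspen-study synthetic study shared across tests."""
    return simulate_study(SimulationParams.aspen_study(), seed=1)


@pytest.fixture(scope="session")
def aspen_matrix(demo_study):
    return filter_aspen_associated(demo_study.community, demo_study.traits)


@pytest.fixture(scope="session")
def small_params():
    """A reduced pool for fast simulation-heavy tests."""
    return SimulationParams(
        pool={
            "specialist": {"wood_feeder": 2, "fungivore": 3,
                           "predator": 1, "omnivore_saprophage": 1},
            "generalist": {"wood_feeder": 5, "fungivore": 10,
                           "predator": 10, "omnivore_saprophage": 3},
        },
    )


def random_community_long(rng, n_traps=5, n_years=4, n_species=8,
                          p_zero=0.5, max_count=20):
    """Long-form random community rows (explicit zeros included)."""
    rows = []
    for t in range(n_traps):
        for y in range(1, n_years + 1):
            for s in range(n_species):
                if rng.random() < p_zero:
                    continue
                rows.append(
                    dict(trap=f"t{t}", year=y, species=f"sp{s}",
                         count=int(rng.integers(0, max_count)))
                )
    if not rows:  # ensure non-empty
        rows.append(dict(trap="t0", year=1, species="sp0", count=1))
    return pd.DataFrame(rows)
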