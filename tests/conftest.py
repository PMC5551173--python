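import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")

from carmap import build_lattice_graph
from carmap.mcmc import McmcConfig
from carmap.model import DiseaseMapModel
from carmap.simulate import generate_study


@pytest.fixture(scope="session")
def lattice3():
    return build_lattice_graph(3, 3)


@pytest.fixture(scope="session")
def pair_graph():
    from carmap.graphs import AreaGraph

    return AreaGraph([[1], [0]])


@pytest.fixture(scope="session")
def small_quarterly_fit():
    """A small quarterly seasonal fit shared by effect-extraction tests.

    6x6 lattice, 12 quarterly periods, inflated expected counts so the
    seasonal effects are well identified at this size.
    """
    study = generate_study(
        "desk",
        rows=6,
        cols=6,
        n_periods=12,
        events_per_person=0.03,  # strong data for a well-powered small fit
        truth={
            "mu": -0.2,
            "beta": (-0.3, 0.3, 0.5),
            "sigma_phi": 0.15,
            "sigma_theta": 0.3,
            "sigma_alpha": 0.1,
            "rho": 0.5,
        },
        seed=11,
    )
    model = DiseaseMapModel(
        study.panel, study.graph, variant="st_quarterly", expected=study.expected
    )
    result = model.fit(
        config=McmcConfig(n_chains=2, n_iter=2_000, burn_in=500, seed=11)
    )
    return study, result


@pytest.fixture(scope="session")
def conjugate_fit():
    """Degenerate no-random-effects fit with a Gamma closed-form posterior."""
    from carmap.data import CountPanel, ExpectedCounts

    graph = build_lattice_graph(2, 2)
    counts = np.array([[30], [20], [25], [25]])  # total 100
    expected = ExpectedCounts(np.full((4, 1), 22.5))  # total 90
    panel = CountPanel(counts=counts, populations=np.ones(4, dtype=int))
    model = DiseaseMapModel(
        panel,
        graph,
        variant="spatial",
        expected=expected,
        fixed={"sigma_phi": 0.0, "sigma_theta": 0.0},
    )
    return model.fit(config=McmcConfig(n_chains=3, n_iter=4_000, burn_in=500, seed=5))
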