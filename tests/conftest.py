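import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from domcal import (
    DomainTotals,
    PopulationFrame,
    PopulationSpec,
    generate_population,
    load_table1_fixture,
)


@pytest.fixture(scope="session")
def table1() -> DomainTotals:
    return load_table1_fixture()


@pytest.fixture(scope="session")
def study_frame(table1) -> PopulationFrame:
    """Table-1-scaled synthetic population: 203 units, 6 domains, ~30% NR."""
    return generate_population(PopulationSpec(target_totals=table1, seed=11))


@pytest.fixture(scope="session")
def proportional_frame() -> PopulationFrame:
    """Noiseless y = beta*x population (proportionality identities)."""
    spec = PopulationSpec(
        domain_sizes=(12, 9, 14), nonresponse_rate=0.3,
        noise_scale=0.0, link_slope=2.5, seed=5,
    )
    return generate_population(spec)


@pytest.fixture(scope="session")
def toy_frame() -> PopulationFrame:
    """Small fixed 30-unit frame with two domains and fixed strata."""
    rng = np.random.default_rng(42)
    n = 30
    x = rng.lognormal(0.0, 0.8, n) * 10
    y = 1.5 * x * rng.lognormal(-0.02, 0.2, n)
    stratum = np.array(
        [("NR" if i % 3 == 0 else "R") for i in range(n)], dtype=object)
    domain = np.array([1] * 18 + [2] * 12)
    return PopulationFrame(
        unit_id=np.arange(1, n + 1), domain=domain, y=y, x=x, stratum=stratum)
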