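import numpy as np
import pytest

import bgindex as bg


@pytest.fixture(scope="session")
def small_study():
    """A small scenario-D-style dataset (n=300) for fast fitting tests."""
    scenario = bg.build_scenario("D", 3, "moderate", n=300)
    data = bg.generate_dataset(scenario, 7)
    return scenario, data


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_params(rng, groups, p=0):
    """A random valid parameter point for density tests."""
    weights = [rng.dirichlet(np.ones(c)) for c in groups.sizes]
    return bg.ModelParams(
        beta0=rng.normal(scale=0.5),
        betas=rng.normal(scale=0.5, size=groups.n_groups),
        weights=weights,
        phi=rng.normal(scale=0.5, size=p) if p else None,
    )
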