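from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from eggsink import HostParams, ModelParams, ParasitoidParams, PopulationState

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def defaults() -> ModelParams:
    """The packaged default parameterization of the aphid-parasitoid system."""
    return ModelParams.paper_defaults()


def random_params(rng: np.random.Generator) -> ModelParams:
    """A random valid parameter set spanning a broad, biologically sane box."""

    def host() -> HostParams:
        s = rng.uniform(0, 1)
        return HostParams(
            r=rng.uniform(0.2, 2.5),
            K=rng.uniform(100, 2000),
            a=rng.uniform(0, 2),
            s=s,
            mu=rng.uniform(0, 1 - s),
        )

    return ModelParams(
        host1=host(),
        host2=host(),
        parasitoid=ParasitoidParams(
            beta=rng.uniform(1, 50),
            k_agg=rng.uniform(0.1, 5),
            X=rng.uniform(0.05, 1),
        ),
    )


def random_state(rng: np.random.Generator, scale: float = 2000.0) -> PopulationState:
    return PopulationState(*rng.uniform(0, scale, size=3))
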