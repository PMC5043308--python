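import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from petoscan import (
    SyntheticConfig,
    generate_function_matrix,
    generate_species,
    generate_tree,
)


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=0)


@pytest.fixture(scope="session")
def cohort():
    """One default synthetic cohort shared across read-only tests."""
    cfg = SyntheticConfig(seed=42)
    species = generate_species(cfg)
    matrix, truth, hierarchy = generate_function_matrix(species, cfg)
    tree = generate_tree(cfg.n_species, cfg.seed)
    return {
        "cfg": cfg,
        "species": species,
        "matrix": matrix,
        "truth": truth,
        "hierarchy": hierarchy,
        "tree": tree,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
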