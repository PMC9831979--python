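import numpy as np
import pytest

from muscleq import generate_phantom, load_reference_cohort, small_test_spec


@pytest.fixture(scope="session")
def reference_table():
    return load_reference_cohort()


@pytest.fixture(scope="session")
def small_control_phantom():
    """Reduced-grid control-like phantom: ring fat only, moderate noise."""
    spec = small_test_spec(seed=11, sigma=30.0)
    pair, lc, truth = generate_phantom(spec)
    return spec, pair, lc, truth


@pytest.fixture(scope="session")
def small_disease_phantom():
    """Reduced-grid disease-like phantom: ring plus intramuscular clumps."""
    spec = small_test_spec(seed=23, sigma=30.0, n_clumps=6, clump_radius_mm=(0.6, 1.2))
    pair, lc, truth = generate_phantom(spec)
    return spec, pair, lc, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
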