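import pandas as pd
import pytest

import mztstage as mz


@pytest.fixture(scope="session")
def cfg0():
    """Noise-free default-size simulation config."""
    return mz.SimulationConfig(seed=9, noise_dispersion=0.0)


@pytest.fixture(scope="session")
def cfg():
    """Default (noisy) simulation config."""
    return mz.SimulationConfig(seed=9)


@pytest.fixture(scope="session")
def ref0(cfg0):
    reference, truth = mz.simulate_reference(cfg0)
    return reference, truth


@pytest.fixture(scope="session")
def ruler0(ref0):
    reference, truth = ref0
    return mz.compile_ruler(reference, truth.to_gene_class())


@pytest.fixture(scope="session")
def refn(cfg):
    reference, truth = mz.simulate_reference(cfg)
    return reference, truth


@pytest.fixture(scope="session")
def rulern(refn):
    reference, truth = refn
    return mz.compile_ruler(reference, truth.to_gene_class())


@pytest.fixture
def tiny_matrix():
    df = pd.DataFrame(
        {"s1": [10.0, 5.0, 1.0], "s2": [8.0, 6.0, 2.0]},
        index=["g1", "g2", "g3"],
    )
    return mz.ExpressionMatrix(df)
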