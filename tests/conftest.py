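import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20230915)


def sample_gp_observations(inputs, spec, noise_variance, rng):
    """Draw y ~ N(0, K + noise*I) for a known kernel (simulation oracle)."""
    from demobo import kernel_matrix

    K = kernel_matrix(spec, inputs, inputs) + noise_variance * np.eye(len(inputs))
    L = np.linalg.cholesky(K + 1e-12 * np.eye(len(inputs)))
    return L @ rng.standard_normal(len(inputs))
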