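import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import directdeps as dd

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def planted_raster():
    """Planted logistic network: output 0 driven by neurons {2,5,7}, weights (2,2,-2)."""
    raster, truth = dd.gen_logistic_network(
        10, (2, 5, 7), (2.0, 2.0, -2.0), -2.0, 0.3, 100_000, seed=7
    )
    return raster, truth


@pytest.fixture(scope="session")
def planted_model(planted_raster):
    raster, truth = planted_raster
    return dd.fit(raster, 0, truth.planted_inputs)


def random_weighted_instance(rng, n):
    """Random joint weighted raster (neuron 0 = output) over all 2^n input configs.

    Returns (raster, input_configs, config_weights, output_conditional) so the
    same instance can feed both the sample-based fitter and the enumeration
    oracle.
    """
    K = 2**n
    X = np.array([[(k >> i) & 1 for i in range(n)] for k in range(K)], dtype=float)
    w = rng.dirichlet(np.ones(K))
    q = rng.uniform(0.05, 0.95, K)
    cols, wts = [], []
    for k in range(K):
        cols.append(np.concatenate(([1], X[k])))
        wts.append(w[k] * q[k])
        cols.append(np.concatenate(([0], X[k])))
        wts.append(w[k] * (1 - q[k]))
    raster = dd.WeightedRaster(np.array(cols, dtype=np.uint8).T, np.array(wts), 1.0)
    return raster, X, w, q
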