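import numpy as np
import pytest

from fluxbridge import (
    NetworkConfig,
    build_climatologies,
    default_registry,
    generate_network,
    preprocess_records,
)


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_network():
    """One small deterministic network shared across tests: 8 flux + 4 met
    stations, one (leap) year, default noise."""
    cfg = NetworkConfig(
        n_flux_stations=8, n_met_stations=4, years=(2012,), seed=11
    )
    metas, records, truths = generate_network(cfg)
    return cfg, metas, records, truths


@pytest.fixture(scope="session")
def small_processed(small_network, registry):
    _, metas, records, _ = small_network
    return metas, preprocess_records(records, registry)


@pytest.fixture(scope="session")
def small_climatologies(small_processed, registry):
    _, records = small_processed
    return build_climatologies(records, registry)


@pytest.fixture()
def rng():
    return np.random.default_rng(20_240_601)
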