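import numpy as np
import pytest

import geogen as gg


@pytest.fixture(scope="session")
def planar_mvn_data():
    """Model-true Gaussian data on a small planar configuration (no
    admixture), shared by inference tests."""
    rng = np.random.default_rng(2024)
    K = 8
    coords = rng.uniform(0.0, 5.0, size=(K, 2))
    locs = gg.LocationSet(coords, metric="euclidean")
    params = gg.ModelParams(
        cov=gg.CovParams(alpha0=1.0, alpha1=0.5, alpha2=1.0),
        eta=np.full(K, 0.05),
        locations=locs,
        admixture=gg.AdmixtureParams(w=np.zeros(K), sources=locs),
    )
    data = gg.simulate_mvn(params, sbar=np.full(K, 10.0), n_loci=3000,
                           rng=rng)
    return params, data


@pytest.fixture(scope="session")
def planar_priors(planar_mvn_data):
    params, _ = planar_mvn_data
    return gg.default_priors(params.locations)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
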