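import pytest

import microsolv as m


@pytest.fixture(scope="session")
def truth():
    return m.default_ground_truth()


@pytest.fixture(scope="session")
def noiseless_designs():
    return {
        "parent": m.ScanDesign.indole_channels(noise_frac=0.0),
        "fragment": m.ScanDesign.indole_channels(noise_frac=0.0),
        "water": m.ScanDesign.water_channel(noise_frac=0.0),
    }


@pytest.fixture(scope="session")
def noiseless_curves(truth, noiseless_designs):
    return m.generate_ion_yield_scan(truth, noiseless_designs, seed=1)


@pytest.fixture(scope="session")
def noiseless_fit(noiseless_curves):
    """Global fit of exact (noise-free) synthetic data; shared because the
    fit re-integrates the density-matrix equations at every iteration."""
    return m.fit_reaction_model(noiseless_curves)


@pytest.fixture(scope="session")
def default_trace(truth):
    return m.integrate_bloch(truth.scheme, truth.pulse, -5.0, 145.0)
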