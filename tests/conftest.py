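import numpy as np
import pytest

import adashape as ada


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260927)


def random_configuration(rng, k=8, scale=30.0):
    """A well-conditioned random landmark configuration (mm)."""
    return ada.ConfigurationMatrix(rng.normal(size=(k, 3)) * scale)


@pytest.fixture(scope="session")
def concentrated_ensemble():
    """Ten specimens that are small perturbations of one base shape, so the
    ensemble is concentrated around its Procrustes mean (the regime the
    tangent approximation assumes)."""
    rng = np.random.default_rng(7)
    base = rng.normal(size=(12, 3)) * 40.0
    return [
        ada.ConfigurationMatrix(base + rng.normal(size=(12, 3)) * 2.0, f"s{i}")
        for i in range(10)
    ]


@pytest.fixture(scope="session")
def templates():
    return ada.make_archetypal_shapes(3, 40, seed=11)


@pytest.fixture(scope="session")
def planted_clean(templates):
    """Zero-noise, identity-transform ensemble: pure tangent-space mixtures."""
    return ada.simulate_ensemble(
        templates, 30, concentration=1.0, noise_sd=0.0, transform_ranges=None, seed=5
    )
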