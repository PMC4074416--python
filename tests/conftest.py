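import numpy as np
import pytest

import nephroplan as npl


@pytest.fixture(scope="session")
def small_spec():
    """Compact phantom (0.8 mm spacing, reduced anatomy) for fast pipeline tests.

    Geometry is scaled so the exact 2.5 mm tumor-tract surface gap of the
    full-size default is preserved.
    """
    return npl.PhantomSpec(
        shape=(88, 72, 64),
        spacing=(0.8, 0.8, 0.8),
        kidney_center=(34.0, 28.0, 25.0),
        kidney_semi_axes=(30.0, 24.0, 20.0),
        tumor_center=(46.0, 28.0, 25.0),
        tumor_radius=9.0,
        tract_polyline=(
            (16.0, 14.0, 23.0),
            (32.5, 20.0, 25.0),
            (32.5, 36.0, 25.0),
            (16.0, 42.0, 27.0),
        ),
        tract_radius=2.0,
        noise_sd=15.0,
        rng_seed=42,
    )


@pytest.fixture(scope="session")
def small_phantom(small_spec):
    """(volume, masks, analytic_gap) for the compact phantom."""
    return npl.generate_phantom(small_spec)


@pytest.fixture(scope="session")
def noise_free_phantom(small_spec):
    import dataclasses

    spec = dataclasses.replace(small_spec, noise_sd=0.0)
    return spec, npl.generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
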