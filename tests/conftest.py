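import numpy as np
import pytest

import hypoxiq as hx


@pytest.fixture(scope="session")
def cohort():
    """The packaged 15-patient HNSCC cohort."""
    return hx.load_packaged_cohort()


@pytest.fixture(scope="session")
def report(cohort):
    """Default pipeline run on the packaged cohort (deterministic)."""
    return hx.run_pipeline(cohort)


@pytest.fixture(scope="session")
def clean_phantom():
    """A small zero-noise phantom with known ground truth."""
    spec = hx.PhantomSpec(
        shape=(16, 32, 32),
        tumor_center=(8, 16, 16),
        tumor_radii=(4.0, 6.0, 6.0),
        hypoxic_fraction=0.4,
        noise_sd=0.0,
        seed=7,
    )
    return spec, hx.generate_phantom(spec)


@pytest.fixture()
def rng():
    return np.random.default_rng(2026)
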