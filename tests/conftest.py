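import numpy as np
import pytest

from evflux import (SyntheticImageSpec, SyntheticProteomeSpec,
                    generate_abundance_matrix, generate_flux_field,
                    generate_viability_field)


@pytest.fixture(scope="session")
def flux_field_truth():
    """Default segmentation-grade flux field (5 cells + debris, seed 1)."""
    return generate_flux_field(SyntheticImageSpec(seed=1))


@pytest.fixture(scope="session")
def noiseless_flux_field_truth():
    spec = SyntheticImageSpec(noise_sd=0.0, background_level=0.0, seed=2)
    return generate_flux_field(spec)


@pytest.fixture(scope="session")
def viability_field_truth():
    """50 well-separated Hoechst/PI blobs, 10% dead, seed 3."""
    return generate_viability_field(SyntheticImageSpec.viability_defaults(seed=3))


@pytest.fixture(scope="session")
def clean_proteome():
    """Complete (no missingness) null matrix for calibration checks."""
    spec = SyntheticProteomeSpec(n_proteins=500, de_fraction=0.0,
                                 missing_midpoint=None, seed=11)
    return generate_abundance_matrix(spec)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
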