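import numpy as np
import pytest

from aslrest import synth

# Desk-scale acquisitions for unit tests: same TRs as the study protocol but
# shorter runs and a smaller grid, so every test fixture builds in well under
# a second.  Band 0.01-0.08 Hz still holds >= 5 FFT bins on both grids.
SMALL_SHAPE = (16, 16, 8)
SMALL_CV = synth.AcquisitionSpec(SMALL_SHAPE, (3.0, 3.0, 3.0), 0.9, 80, "cvBOLD")
SMALL_ASL = synth.AcquisitionSpec(SMALL_SHAPE, (3.0, 3.0, 3.0), 4.0, 40, "ASL")


@pytest.fixture(scope="session")
def small_subject():
    """One default-noise subject on the small grid."""
    return synth.generate_subject(SMALL_CV, SMALL_ASL, synth.GeneratorConfig(), seed=42)


@pytest.fixture(scope="session")
def clean_subject():
    """Noise-free, drift-free subject with a single planted network."""
    design = synth.GeneratorConfig(n_networks=1, noise_sd_cv=0.0, noise_sd_asl=0.0,
                                   drift_sd_per_s=0.0)
    return synth.generate_subject(SMALL_CV, SMALL_ASL, design, seed=43)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
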