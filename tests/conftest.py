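import numpy as np
import pytest

from mammodose.materials import builtin_materials
from mammodose.phantom import PhantomSpec, build_phantom
from mammodose.spectrum import BeamConfig, filter_spectrum, generate_spectrum


@pytest.fixture(scope="session")
def registry():
    return builtin_materials()


@pytest.fixture(scope="session")
def default_beam():
    return BeamConfig()


@pytest.fixture(scope="session")
def rh_tube_spectrum(registry):
    """Tube + 0.06 mm Rh (the source fed to transport; paddle is part of
    the tracked geometry)."""
    s = generate_spectrum(BeamConfig(extra_filter="Rh"))
    return filter_spectrum(s, registry["rhodium"], 0.06)


@pytest.fixture(scope="session")
def phantom_4cm_50():
    return build_phantom(PhantomSpec(4.0, 0.50))


@pytest.fixture(scope="session")
def study_grid():
    """The full 18-cell study plus its mixture companion at the
    10^6-history scale; shared by the acceptance tests."""
    from mammodose.dose import run_study
    return run_study(master_seed=0, histories_per_cell=1_000_000,
                     batches=20, include_mixture=True)


def seeded_rng(seed=1234):
    return np.random.default_rng(seed)
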