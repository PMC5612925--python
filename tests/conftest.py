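import numpy as np
import pytest

from lvtraj import RegistrationSpec, SimulationSpec, generate_cohort, register_sequence
from lvtraj.transport import run_ls_pca


@pytest.fixture(scope="session")
def small_spec():
    return SimulationSpec(n_per_group=6, rings=5, meridians=8, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_spec):
    return generate_cohort(small_spec)


@pytest.fixture(scope="session")
def registered_small(small_cohort):
    spec = RegistrationSpec()
    return {surf: [register_sequence(c.surface(surf), spec) for c in small_cohort]
            for surf in ("endo", "epi")}


@pytest.fixture(scope="session")
def transported_small(registered_small):
    return run_ls_pca(registered_small["endo"], mode="sss")


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
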