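import numpy as np
import pytest

from t2ivim.presets import (B_CONSENSUS_LIVER, B_SET_1, TE_SET_1, TE_SET_2,
                            T2_FLUID_GRID_LIVER, kidney_state, liver_state,
                            simulation_grid)
from t2ivim.signal_models import AcquisitionGrid


@pytest.fixture(scope="session")
def liver():
    return liver_state()


@pytest.fixture(scope="session")
def kidney():
    return kidney_state()


@pytest.fixture(scope="session")
def grid_16b_6te():
    """16 b-values x TE set 1 (47-72 ms) at TR 4000 ms."""
    return simulation_grid()


@pytest.fixture(scope="session")
def grid_consensus_3te():
    return AcquisitionGrid(b_values=B_CONSENSUS_LIVER,
                           te_values=(50.0, 60.0, 100.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_liver_disc_phantom(n=20, sigma=0.0, seed=7, delta_t2=30.0):
    """Liver-like disc on empty background, scaled so the b=0 signal at the
    reference TE is 1 (sigma is then 1/SNR at that anchor)."""
    from t2ivim.signal_models import t2ivim_signal
    from t2ivim.simulator import NoiseModel, make_image_phantom

    grid = AcquisitionGrid(b_values=B_SET_1, te_values=TE_SET_1)
    yy, xx = np.mgrid[0:n, 0:n]
    layout = ((yy - n / 2) ** 2 + (xx - n / 2) ** 2 < (n * 0.35) ** 2).astype(int)
    base = liver_state(delta_t2=delta_t2)
    anchor = t2ivim_signal(base.ivim, base.relax.T2_tissue, base.relax.T2_fluid,
                           1.0, 0.0, grid.reference_te)
    st = liver_state(delta_t2=delta_t2, s0=1.0 / anchor)
    stack = make_image_phantom(layout, {1: st}, grid,
                               NoiseModel(sigma=sigma, seed=seed))
    return stack, layout, st


@pytest.fixture(scope="session")
def liver_disc_phantom():
    """Factory fixture for the two-region liver phantom."""
    return make_liver_disc_phantom
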