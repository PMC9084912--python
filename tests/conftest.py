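import numpy as np
import pytest

from podcpm.config import SimulationConfig
from podcpm.core import ContactEnergyTable, CPMState


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_state(owner, j_cell_med=4.0, j_cell_cell=6.0, target_area=None,
               lambda_area=1.0, n_types_cells=None):
    """Build a consistent CPMState from an explicit owner matrix."""
    owner = np.asarray(owner, dtype=np.int32)
    n_cells = int(owner.max())
    h, w = owner.shape
    contact = ContactEnergyTable.two_type(j_cell_med, j_cell_cell)
    counts = np.bincount(owner.ravel(), minlength=n_cells + 1)
    if target_area is None:
        target_area = 1.0
    state = CPMState(w, h, n_cells, contact, target_area, lambda_area)
    for y in range(h):
        for x in range(w):
            if owner[y, x] != 0:
                state.add_site(int(owner[y, x]), x, y)
    assert np.array_equal(
        np.bincount(state.owner.ravel(), minlength=n_cells + 1), counts)
    return state


def random_state(rng, size=20, n_cells=4, fill=0.4, **kw):
    """Random lattice configuration (not necessarily connected cells)."""
    owner = np.zeros((size, size), dtype=np.int32)
    n_sites = int(fill * size * size)
    idx = rng.choice(size * size, size=n_sites, replace=False)
    owner.ravel()[idx] = rng.integers(1, n_cells + 1, size=n_sites)
    kw.setdefault("target_area", float(n_sites) / n_cells)
    return make_state(owner, **kw)


@pytest.fixture
def small_config():
    return SimulationConfig(width=40, height=40, n_cells=3, total_mcs=60,
                            equilibration_mcs=20, model="base", seed=1)
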