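import warnings

import numpy as np
import pytest

from capforge.membrane import (CapillarySpec, cut_pores, subdivision_grid,
                               sweep_shell, thicken)
from capforge.pathgen import CenterlinePath


@pytest.fixture(scope="session")
def straight_path():
    """200 µm straight tube axis along +x at z = 60 µm."""
    return CenterlinePath([[-100.0, 0.0, 60.0], [100.0, 0.0, 60.0]], degree=1)


@pytest.fixture(scope="session")
def circle_path():
    th = np.linspace(0.0, 2.0 * np.pi, 96)
    pts = np.c_[300.0 * np.cos(th), 300.0 * np.sin(th), np.zeros_like(th)]
    return CenterlinePath(pts, closed=True)


@pytest.fixture(scope="session")
def small_spec():
    """Coarse capillary spec keeping meshes tiny in unit tests."""
    return CapillarySpec(lumen_diameter=40.0, pore_diameter=10.0,
                         pore_spacing=10.0, membrane_thickness=10.0)


@pytest.fixture(scope="session")
def small_grid(straight_path, small_spec):
    return subdivision_grid(straight_path.path_length, small_spec)


@pytest.fixture(scope="session")
def small_shell(straight_path, small_grid, small_spec):
    return sweep_shell(straight_path, small_grid, small_spec)


@pytest.fixture(scope="session")
def small_pored(small_shell, small_grid, small_spec):
    return cut_pores(small_shell, small_grid, small_spec)


@pytest.fixture(scope="session")
def small_solid(small_pored):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return thicken(small_pored)
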