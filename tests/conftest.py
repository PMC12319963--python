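import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for tests/oracles.py

from mtmskit.geometry import SphericalHeadModel, WindingPath


@pytest.fixture(scope="session")
def rat_head_small():
    """13.7-mm rat cortex sphere at 15-mm standoff, coarse 642-vertex mesh."""
    return SphericalHeadModel.at_standoff(0.0137, 0.015, 642)


@pytest.fixture
def circular_loop():
    """Closed 20-mm-radius circular loop in the coil plane (z = 0)."""

    def make(radius=0.02, center=(0.0, 0.0, 0.0), n=129, tilt=0.0):
        th = np.linspace(0.0, 2.0 * np.pi, n)
        pts = np.column_stack(
            [radius * np.cos(th), radius * np.sin(th), np.zeros_like(th)]
        )
        c, s = np.cos(tilt), np.sin(tilt)
        rot = np.array([[1, 0, 0], [0, c, -s], [0, s, c]])
        pts = pts @ rot.T + np.asarray(center)
        pts[-1] = pts[0]
        return pts

    return make


@pytest.fixture
def single_loop_winding(circular_loop):
    return WindingPath([circular_loop()], [1], [0], wire_diameter=1.7e-3)
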