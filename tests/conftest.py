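"""Shared synthetic fixtures.

Everything is generated programmatically; no binary assets.
"""

import numpy as np
import pytest

from neurofields import arrays, currents, morphology, templates


def lift(m: morphology.Morphology, height: float = 15.0) -> morphology.Morphology:
    """Suspend a morphology ``height`` um above the sensor plane."""
    dz = np.array([0.0, 0.0, height])
    return morphology.Morphology(
        [
            morphology.Segment(s.start + dz, s.end + dz, s.radius, s.parent, s.label)
            for s in m.segments
        ],
        m.soma_position + dz,
    )


@pytest.fixture(scope="session")
def gaussian_wave():
    return currents.gaussian_ap(167.0, 100.0)


@pytest.fixture(scope="session")
def spike_wave():
    """Sharp-front wave used for polarity-sensitive fixtures."""
    return currents.asymmetric_ap(30.0, 150.0, 100.0)


@pytest.fixture(scope="session")
def t_grid():
    return np.arange(64) * 0.03125  # 2 ms window


@pytest.fixture(scope="session")
def ball_stick_currents(gaussian_wave, t_grid):
    m = lift(morphology.make_ball_stick(400.0, 2.0, 20.0, 10.0))
    c = currents.propagate_ap(m, gaussian_wave, 0.3, t_grid, center_start=-200.0)
    return m, c


@pytest.fixture(scope="session")
def small_grid():
    return arrays.make_sensor_grid(12, 12, 50.0)


@pytest.fixture(scope="session")
def centered_templates(gaussian_wave, t_grid):
    """phi/Bz templates of a soma-centered elongated cell on a dense grid."""
    sensors = arrays.make_sensor_grid(60, 60, 10.0)
    m = lift(morphology.make_ball_stick(280.0, 2.0, 20.0, 10.0))
    c = currents.propagate_ap(m, gaussian_wave, 0.3, t_grid, center_start=-180.0)
    return {
        mod: templates.compute_template(c, sensors, mod, cell_id=0)
        for mod in ("phi", "Bz")
    }
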