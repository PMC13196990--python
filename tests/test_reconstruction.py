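import numpy as np
import pytest

from neurofields import currents, reconstruction
from neurofields.arrays import make_sensor_grid
from neurofields.errors import InvalidParameterError, NoBoundaryError
from neurofields.morphology import (
    Morphology,
    Segment,
    make_ball_stick,
    make_branched_cell,
    transform_morphology,
)
from neurofields.reconstruction import (
    PolarityLabels,
    add_template_noise,
    cnbe,
    gnbe,
    reconstruction_error,
    sensor_polarity,
)
from neurofields.templates import SpikeTemplate, compute_template

from conftest import lift


def bz_template(values, n=20, pitch=50.0):
    return SpikeTemplate(values, make_sensor_grid(n, n, pitch), 0.03125, "Bz")


def centered_axon(pitch, spike_wave, t_grid, length=500.0):
    """Straight +x axon centered on a 20x20 array, 15 um up."""
    m = lift(
        transform_morphology(
            make_ball_stick(length, 2, 20, 10), 0.0, (-length / 2, 0.0)
        )
    )
    c = currents.propagate_ap(
        m, spike_wave, 0.3, t_grid, center_start=-150.0, attenuation_length=200.0
    )
    sensors = make_sensor_grid(20, 20, pitch)
    return m, compute_template(c, sensors, "Bz")


@pytest.fixture(scope="module")
def axon_fixture(spike_wave, t_grid):
    return centered_axon(50.0, spike_wave, t_grid)


@pytest.fixture(scope="module")
def dendrite_fixture(spike_wave, t_grid):
    """Trunk plus an oblique opposing dendrite (near-soma inversion)."""
    m = lift(
        transform_morphology(
            make_branched_cell(
                500, 1, 300, seed=1, branch_diameter=1.5, segment_length=10
            ),
            0.0,
            (-250.0, 0.0),
        )
    )
    c = currents.propagate_ap(
        m, spike_wave, 0.3, np.arange(64) * 0.03125,
        center_start=-150.0, attenuation_length=200.0,
    )
    sensors = make_sensor_grid(20, 20, 50.0)
    return m, compute_template(c, sensors, "Bz")


class TestSensorPolarity:
    def test_peak_sign(self):
        vals = np.zeros((400, 4))
        vals[:, 1] = 3.0
        vals[:, 2] = -1.0
        labels = sensor_polarity(bz_template(vals))
        assert np.all(labels.labels == 1)

    def test_negation_flips_labels(self, axon_fixture):
        _, tpl = axon_fixture
        l1 = sensor_polarity(tpl)
        l2 = sensor_polarity(bz_template(-tpl.values))
        assert np.array_equal(l1.labels, -l2.labels)

    def test_zero_sensor_excluded(self):
        vals = np.ones((400, 4))
        vals[7] = 0.0
        labels = sensor_polarity(bz_template(vals))
        assert labels.positions.shape[0] == 399

    def test_requires_bz(self):
        t = SpikeTemplate(
            np.ones((16, 2)), make_sensor_grid(4, 4, 50.0), 0.1, "phi"
        )
        with pytest.raises(InvalidParameterError):
            sensor_polarity(t)


class TestGNBE:
    def test_half_plane_split(self):
        arr = make_sensor_grid(20, 20, 50.0)
        labels = PolarityLabels(
            positions=arr.positions[:, :2],
            labels=np.where(arr.positions[:, 0] < 0, -1, 1),
            power=np.ones(arr.n_sensors),
        )
        est = gnbe(labels)
        # boundary within half a pitch of the line x = 0
        assert np.max(np.abs(est.boundary[:, 0])) < 25.0

    def test_noiseless_axon_boundary(self, axon_fixture):
        m, tpl = axon_fixture
        est = gnbe(sensor_polarity(tpl))
        err, _, _ = reconstruction_error(est, m)
        assert err < 50.0  # smaller than the sensor pitch

    def test_single_polarity_rejected(self):
        arr = make_sensor_grid(5, 5, 50.0)
        labels = PolarityLabels(
            positions=arr.positions[:, :2],
            labels=np.ones(25, dtype=int),
            power=np.ones(25),
        )
        with pytest.raises(NoBoundaryError):
            gnbe(labels)

    def test_scale_invariance(self, axon_fixture):
        _, tpl = axon_fixture
        b1 = gnbe(sensor_polarity(tpl)).boundary
        b2 = gnbe(sensor_polarity(bz_template(5.0 * tpl.values))).boundary
        assert np.allclose(b1, b2)

    def test_negation_leaves_boundary_unchanged(self, axon_fixture):
        _, tpl = axon_fixture
        b1 = gnbe(sensor_polarity(tpl)).boundary
        b2 = gnbe(sensor_polarity(bz_template(-tpl.values))).boundary
        # labels flip jointly; the separating set is the same curve
        d = np.sqrt(
            np.min(
                np.sum((b1[:, None, :] - b2[None, :, :]) ** 2, axis=2), axis=1
            )
        )
        assert np.max(d) < 25.0


class TestReconstructionError:
    def test_boundary_through_midpoints(self):
        m = make_ball_stick(100, 2, 20, 10)
        mids = m.midpoints[1:, :2]  # axon midpoints
        est = reconstruction.BoundaryEstimate(
            boundary=mids, grid_x=np.array([0.0]), grid_y=np.array([0.0]),
            decision=np.zeros((1, 1)),
        )
        err, _, _ = reconstruction_error(est, m)
        assert err == pytest.approx(0.0)

    def test_offset_boundary(self):
        m = make_ball_stick(100, 2, 20, 10)
        mids = m.midpoints[1:, :2] + np.array([0.0, 7.0])
        est = reconstruction.BoundaryEstimate(
            boundary=mids, grid_x=np.array([0.0]), grid_y=np.array([0.0]),
            decision=np.zeros((1, 1)),
        )
        err, _, _ = reconstruction_error(est, m)
        assert err == pytest.approx(7.0)

    def test_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        segs = [Segment([0, 0, 0], [0, 0, 0], 10.0, None, "soma")]
        p = np.zeros(3)
        for i in range(10):
            q = p + rng.uniform(5, 20, 3) * [1, 0.3, 0]
            segs.append(Segment(p, q, 1.0, i, "axon"))
            p = q
        m = Morphology(segs, np.zeros(3))
        boundary = rng.uniform(-100, 200, (57, 2))
        est = reconstruction.BoundaryEstimate(
            boundary=boundary, grid_x=np.array([0.0]), grid_y=np.array([0.0]),
            decision=np.zeros((1, 1)),
        )
        err, _, per = reconstruction_error(est, m)
        # exhaustive scan oracle
        mids = m.midpoints[1:, :2]
        expected = []
        for mid in mids:
            best = min(np.hypot(*(mid - b)) for b in boundary)
            expected.append(best)
        assert np.allclose(per, expected, atol=1e-6)
        assert err == pytest.approx(np.mean(expected), abs=1e-6)

    def test_empty_boundary_rejected(self):
        m = make_ball_stick(100, 2, 20, 10)
        est = reconstruction.BoundaryEstimate(
            boundary=np.empty((0, 2)), grid_x=np.array([0.0]),
            grid_y=np.array([0.0]), decision=np.zeros((1, 1)),
        )
        with pytest.raises(InvalidParameterError):
            reconstruction_error(est, m)


class TestAddTemplateNoise:
    def test_infinite_snr_unchanged(self, axon_fixture):
        _, tpl = axon_fixture
        noisy = add_template_noise(tpl, np.inf, seed=0)
        assert np.array_equal(noisy.values, tpl.values)

    def test_snr_concentration(self):
        rng = np.random.default_rng(4)
        vals = rng.normal(size=(400, 224))
        tpl = bz_template(vals)
        noisy = add_template_noise(tpl, 20.0, seed=1)
        noise = noisy.values - vals
        snr_db = 10 * np.log10(np.mean(vals**2) / np.mean(noise**2))
        assert snr_db == pytest.approx(20.0, abs=0.2)

    def test_seed_reproducible(self, axon_fixture):
        _, tpl = axon_fixture
        a = add_template_noise(tpl, 10.0, seed=9)
        b = add_template_noise(tpl, 10.0, seed=9)
        assert np.array_equal(a.values, b.values)


class TestCNBE:
    def test_straight_axon_close_to_gnbe(self, axon_fixture):
        m, tpl = axon_fixture
        noisy = add_template_noise(tpl, 20.0, seed=2)
        g = gnbe(sensor_polarity(noisy))
        c = cnbe(noisy, g)
        eg, _, _ = reconstruction_error(g, m)
        ec, _, _ = reconstruction_error(c, m)
        assert abs(ec - eg) < 25.0  # pitch / 2

    def test_hillock_estimate(self, spike_wave):
        sensors = make_sensor_grid(20, 20, 20.0)
        wave = currents.asymmetric_ap(20.0, 150.0, 100.0)
        m = lift(make_ball_stick(300, 2, 20, 5))
        c = currents.propagate_ap(
            m, wave, 0.3, np.arange(32) * 0.03125,
            center_start=-80.0, attenuation_length=75.0,
        )
        tpl = compute_template(c, sensors, "Bz")
        est = cnbe(tpl)
        # true hillock: proximal axon at the soma, (0, 0) in the plane
        assert np.linalg.norm(est.hillock_estimate) < 25.0

    def test_opposing_dendrite_near_soma_improvement(self, dendrite_fixture):
        m, tpl = dendrite_fixture
        g_near, c_near = [], []
        for seed in range(6):
            noisy = add_template_noise(tpl, 20.0, seed=seed)
            g = gnbe(sensor_polarity(noisy))
            c = cnbe(noisy, g)
            _, pdg, peg = reconstruction_error(g, m, "axon")
            _, pdc, pec = reconstruction_error(c, m, "axon")
            g_near.append(np.mean(peg[pdg < 100]))
            c_near.append(np.mean(pec[pdc < 100]))
        assert np.mean(c_near) < np.mean(g_near)

    def test_small_array_scaled_ranks(self, spike_wave, t_grid):
        m = lift(
            transform_morphology(
                make_ball_stick(300, 2, 20, 10), 0.0, (-150.0, 0.0)
            )
        )
        c = currents.propagate_ap(
            m, spike_wave, 0.3, t_grid, center_start=-100.0,
            attenuation_length=200.0,
        )
        sensors = make_sensor_grid(8, 8, 60.0)
        tpl = compute_template(c, sensors, "Bz")
        est = cnbe(tpl)
        assert any("sensors" in w for w in est.warnings)
        assert est.boundary.size > 0


class TestPitchSweep:
    @pytest.mark.parametrize("pitch", [50.0, 75.0, 100.0])
    def test_error_below_pitch_at_20db(self, pitch, spike_wave, t_grid):
        m, tpl = centered_axon(pitch, spike_wave, t_grid)
        errs = []
        for seed in range(4):
            noisy = add_template_noise(tpl, 20.0, seed=seed)
            est = gnbe(sensor_polarity(noisy))
            err, _, _ = reconstruction_error(est, m)
            errs.append(err)
        assert np.mean(errs) < pitch
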