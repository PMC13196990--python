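import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurofields import templates
from neurofields.arrays import make_sensor_grid
from neurofields.errors import InvalidParameterError
from neurofields.templates import (
    SimilarityMap,
    SpikeTemplate,
    compute_template,
    effective_radius,
    rotate_template,
    similarity_map,
    spread_template,
    translate_template,
)


def grid_template(values, pitch=20.0, signal_type="phi", n=None):
    if n is None:
        n = int(np.sqrt(values.shape[0]))
    return SpikeTemplate(values, make_sensor_grid(n, n, pitch), 0.03125, signal_type)


class TestComputeTemplate:
    def test_zero_currents(self, small_grid, ball_stick_currents):
        _, c = ball_stick_currents
        from neurofields.currents import CompartmentCurrents

        c0 = CompartmentCurrents(
            c.positions, c.directions, np.zeros_like(c.I_a),
            np.zeros_like(c.I_m), c.dt,
        )
        t = compute_template(c0, small_grid, "Bz")
        assert np.allclose(t.values, 0)

    def test_default_window_224_columns(self, small_grid, gaussian_wave):
        from neurofields import currents
        from neurofields.morphology import make_ball_stick

        from conftest import lift

        m = lift(make_ball_stick(200, 2, 20, 20))
        t_grid = np.arange(templates.DEFAULT_N_T) * templates.DEFAULT_DT
        c = currents.propagate_ap(m, gaussian_wave, 0.3, t_grid)
        t = compute_template(c, small_grid, "phi")
        assert t.values.shape[1] == 224
        assert t.dt == pytest.approx(0.03125)

    def test_bz_antisymmetry(self, small_grid, ball_stick_currents):
        _, c = ball_stick_currents
        t = compute_template(c, small_grid, "Bz")
        nx, ny = small_grid.shape
        vals = t.values.reshape(ny, nx, -1)
        # +x-aligned axon: Bz at (x, +y) has opposite sign to (x, -y)
        assert np.allclose(vals, -vals[::-1, :, :], rtol=1e-9, atol=1e-12)

    def test_save_load_round_trip(self, tmp_path, small_grid, ball_stick_currents):
        _, c = ball_stick_currents
        t = compute_template(c, small_grid, "phi", cell_id=3)
        path = tmp_path / "tpl.h5"
        t.save(path)
        t2 = SpikeTemplate.load(path)
        assert np.allclose(t.values, t2.values)
        assert t2.signal_type == "phi"
        assert t2.cell_id == 3
        assert t2.sensors.pitch == small_grid.pitch


class TestRotateTemplate:
    def test_rotation_weights_sum_to_one(self):
        arr = make_sensor_grid(10, 10, 20.0)
        op = templates._rotation_operator(arr, 37.0, K=5)
        sums = np.asarray(op.sum(axis=1)).ravel()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_uniform_scalar_invariant(self):
        t = grid_template(np.full((100, 5), 2.5))
        r = rotate_template(t, 73.0)
        assert np.allclose(r.values, 2.5, atol=1e-9)

    def test_zero_rotation_identity(self):
        rng = np.random.default_rng(0)
        t = grid_template(rng.normal(size=(100, 4)))
        r = rotate_template(t, 0.0)
        assert np.allclose(r.values, t.values)

    def test_pure_bx_to_by(self):
        bx = grid_template(np.full((100, 3), 1.0), signal_type="Bx")
        by = grid_template(np.zeros((100, 3)), signal_type="By")
        rx = rotate_template(bx, 90.0, companion=by)
        ry = rotate_template(by, 90.0, companion=bx)
        assert np.allclose(rx.values, 0.0, atol=1e-9)
        assert np.allclose(ry.values, 1.0, atol=1e-9)

    def test_planar_requires_companion(self):
        bx = grid_template(np.ones((100, 3)), signal_type="Bx")
        with pytest.raises(InvalidParameterError):
            rotate_template(bx, 45.0)

    def test_printed_mode_scales_by_k(self):
        rng = np.random.default_rng(1)
        t = grid_template(rng.normal(size=(100, 4)))
        a = rotate_template(t, 30.0, K=5, mode="normalized")
        b = rotate_template(t, 30.0, K=5, mode="printed")
        assert np.allclose(b.values, a.values / 5.0)


class TestTranslateTemplate:
    def test_zero_identity(self):
        rng = np.random.default_rng(2)
        t = grid_template(rng.normal(size=(100, 4)))
        assert np.allclose(translate_template(t, (0, 0)).values, t.values)

    def test_round_trip_away_from_boundary(self):
        rng = np.random.default_rng(3)
        t = grid_template(rng.normal(size=(100, 4)))
        rt = translate_template(translate_template(t, (20, 0)), (-20, 0))
        v = t.values.reshape(10, 10, -1)
        v2 = rt.values.reshape(10, 10, -1)
        assert np.allclose(v2[:, :-1], v[:, :-1])

    def test_norm_non_increasing(self):
        rng = np.random.default_rng(4)
        t = grid_template(rng.normal(size=(100, 4)))
        for delta in ((20, 0), (0, -40), (60, 80)):
            assert translate_template(t, delta).values.std() <= t.values.std() + 1e-12
            assert (
                np.linalg.norm(translate_template(t, delta).values)
                <= np.linalg.norm(t.values) + 1e-12
            )

    def test_snap_with_warning(self):
        t = grid_template(np.ones((100, 2)))
        with pytest.warns(UserWarning, match="snapping"):
            translate_template(t, (27.0, 0.0))


class TestSpreadTemplate:
    def test_default_step_averages_24_rotations(self):
        t = grid_template(np.ones((100, 2)))
        g = spread_template(t)
        assert g.theta_step == 15.0
        assert np.allclose(g.values, 1.0, atol=1e-9)

    def test_radially_symmetric_fixed_point(self):
        arr = make_sensor_grid(11, 11, 20.0)
        r = np.linalg.norm(arr.positions[:, :2], axis=1)
        vals = np.exp(-((r / 60.0) ** 2))[:, None] * np.ones((1, 3))
        t = SpikeTemplate(vals, arr, 0.1, "phi")
        g = spread_template(t)
        # fixed point up to the smoothing bias of the K-nearest IDW
        # resampling (a few percent at this pitch)
        assert np.allclose(g.values, t.values, atol=0.05)
        assert np.corrcoef(g.values[:, 0], t.values[:, 0])[0, 1] > 0.999

    def test_sweep_rotation_invariant(self):
        rng = np.random.default_rng(5)
        t = grid_template(rng.normal(size=(121, 3)), n=11)
        g1 = spread_template(t)
        g2 = spread_template(rotate_template(t, 90.0))
        # equal up to K-nearest tie-breaking at the symmetric angles
        assert np.allclose(g1.values, g2.values, atol=0.05)
        rms = np.sqrt(np.mean((g1.values - g2.values) ** 2))
        assert rms < 0.02 * np.sqrt(np.mean(t.values**2))

    def test_commutes_with_scaling(self):
        rng = np.random.default_rng(6)
        t = grid_template(rng.normal(size=(100, 3)))
        g1 = spread_template(t).values * 3.0
        t3 = grid_template(t.values * 3.0)
        g3 = spread_template(t3).values
        assert np.allclose(g1, g3, rtol=1e-12)

    def test_bad_step(self):
        t = grid_template(np.ones((100, 2)))
        with pytest.raises(InvalidParameterError):
            spread_template(t, theta_step=17.0)


class TestSimilarityMap:
    def test_self_similarity_without_sweep(self):
        rng = np.random.default_rng(7)
        t = grid_template(rng.normal(size=(100, 4)))
        smap = similarity_map(t, t, ([0.0], [0.0]), sweep=False)
        assert smap.values[0, 0] == pytest.approx(1.0)

    def test_negated_template(self):
        rng = np.random.default_rng(8)
        t = grid_template(rng.normal(size=(100, 4)))
        tm = grid_template(-t.values)
        smap = similarity_map(t, tm, ([0.0], [0.0]), sweep=False)
        assert smap.values[0, 0] == pytest.approx(-1.0)

    @given(seed=st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_bounded_on_random_templates(self, seed):
        rng = np.random.default_rng(seed)
        t_n = grid_template(rng.normal(size=(64, 3)), n=8)
        t_m = grid_template(rng.normal(size=(64, 3)), n=8)
        smap = similarity_map(
            t_n, t_m, ([-40.0, 0.0, 40.0], [0.0]), theta_step=90.0
        )
        assert np.all(smap.values <= 1.0 + 1e-9)
        assert np.all(smap.values >= -1.0 - 1e-9)

    def test_zero_norm_rejected(self):
        t = grid_template(np.ones((100, 2)))
        z = grid_template(np.zeros((100, 2)))
        with pytest.raises(InvalidParameterError):
            similarity_map(t, z, ([0.0], [0.0]))

    def test_phi_more_similar_than_bz(self, centered_templates):
        grid = templates.default_displacement_grid(200.0, 40.0)
        means = {}
        for mod in ("phi", "Bz"):
            smap = similarity_map(
                centered_templates[mod], centered_templates[mod], grid
            )
            means[mod] = np.mean(np.abs(smap.values))
        assert means["phi"] > means["Bz"]


class TestEffectiveRadius:
    def _map(self, values, d=20.0):
        n = values.shape[0]
        ax = (np.arange(n) - n // 2) * d
        return SimilarityMap(ax, ax, values, (0, 1), "phi")

    def test_empty_set(self):
        smap = self._map(np.full((5, 5), -0.5))
        assert effective_radius(smap, 0.3) == 0.0

    def test_single_point(self):
        vals = np.zeros((5, 5))
        vals[2, 2] = 0.9
        smap = self._map(vals, d=20.0)
        assert effective_radius(smap, 0.5) == pytest.approx(
            np.sqrt(400.0 / np.pi)
        )

    def test_monotone_in_gamma(self):
        rng = np.random.default_rng(9)
        smap = self._map(rng.uniform(-1, 1, (9, 9)))
        radii = [effective_radius(smap, g) for g in (-0.5, 0.0, 0.25, 0.5, 0.9)]
        assert all(a >= b for a, b in zip(radii, radii[1:]))

    def test_gamma_bounds(self):
        smap = self._map(np.zeros((3, 3)))
        with pytest.raises(InvalidParameterError):
            effective_radius(smap, 1.0)

    def test_phi_radius_larger_than_bz(self, centered_templates):
        grid = templates.default_displacement_grid(200.0, 20.0)
        radii = {}
        for mod in ("phi", "Bz"):
            smap = similarity_map(
                centered_templates[mod], centered_templates[mod], grid
            )
            radii[mod] = {g: effective_radius(smap, g) for g in (0.1, 0.25)}
        assert radii["phi"][0.25] > radii["Bz"][0.25]
        assert radii["phi"][0.1] > radii["Bz"][0.1]
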