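"""Wind rotation, compositing and the enhancement statistic."""

import numpy as np
import pytest

from plumewake.composite import (
    PlumeCompositeModel,
    RotatedComposite,
    WindFieldSeries,
    composite,
    enhancement,
    prevailing_direction,
    radial_asymmetry,
    required_buffer_radius,
    rotate_window,
    stratified_enhancement,
)
from plumewake.grids import GridSpec, RasterField


def constant_winds(u, v, n_days=1, n=6):
    spec = GridSpec(-1.0, -1.0, 0.5, n, n)
    uu = np.full((n_days, 24, n, n), float(u))
    vv = np.full((n_days, 24, n, n), float(v))
    return WindFieldSeries(spec, uu, vv)


class TestPrevailingDirection:
    def test_eastward_flow_is_zero_degrees(self):
        w = prevailing_direction(constant_winds(1, 0), 0.2, 0.3, 0)
        assert w.direction_deg == pytest.approx(0.0)
        assert not w.calm

    def test_northward_flow_is_ninety_degrees(self):
        w = prevailing_direction(constant_winds(0, 1), 0.2, 0.3, 0)
        assert w.direction_deg == pytest.approx(90.0)

    def test_opposing_hours_cancel_to_calm(self):
        spec = GridSpec(-1.0, -1.0, 0.5, 6, 6)
        u = np.zeros((1, 24, 6, 6))
        u[0, 16] = 1.0
        u[0, 17] = -1.0
        u[0, 18] = 1.0
        u[0, 19] = -1.0
        u[0, 20] = 1.0
        u[0, 20] = 1.0  # 5 samples: +1,-1,+1,-1,+1 -> mean 0.2, not calm
        winds = WindFieldSeries(spec, u, np.zeros_like(u))
        w = prevailing_direction(winds, 0.0, 0.0, 0)
        assert not w.calm
        # exact cancellation over an even split
        u2 = np.zeros((1, 24, 6, 6))
        u2[0, 16] = 1.0
        u2[0, 17] = -1.0
        winds2 = WindFieldSeries(spec, u2, np.zeros_like(u2))
        w2 = prevailing_direction(winds2, 0.0, 0.0, 0, hours=(16, 17))
        assert w2.calm
        assert np.isnan(w2.direction_deg)

    def test_speed_is_vector_mean_norm(self):
        w = prevailing_direction(constant_winds(3, 4), 0.0, 0.0, 0)
        assert w.speed == pytest.approx(5.0)


class TestRotateWindow:
    def test_identity_rotation_returns_central_window(self, rng):
        buf = rng.normal(size=(21, 21))
        out = rotate_window(buf, 0.0, 7)
        assert np.allclose(out, buf[3:18, 3:18])

    def test_quarter_turn_nearest_is_exact_permutation(self, rng):
        buf = rng.normal(size=(21, 21))
        out = rotate_window(buf, 90.0, 7, mode="nearest")
        # wind toward north: the +x (downwind) axis of the output samples
        # the +y axis of the buffer -> transpose-like permutation
        center = buf[10, 10]
        assert out[7, 7] == center
        # cell 4 north of center in the buffer appears 4 east in the output
        assert out[7, 7 + 4] == buf[10 + 4, 10]

    def test_plume_north_with_north_wind_lands_downwind(self):
        buf = np.zeros((21, 21))
        buf[10 + 4, 10] = 5.0  # 4 cells north of center
        out = rotate_window(buf, 90.0, 7)
        r, c = np.unravel_index(np.nanargmax(out), out.shape)
        assert (r, c) == (7, 7 + 4)

    def test_buffer_too_small_raises(self):
        with pytest.raises(ValueError, match="buffer radius"):
            rotate_window(np.zeros((15, 15)), 45.0, 7)
        assert required_buffer_radius(7) == 10

    def test_invalid_cells_propagate(self):
        buf = np.full((21, 21), 1.0)
        buf[10, 12] = np.nan
        out = rotate_window(buf, 0.0, 7)
        assert np.isnan(out[7, 9])

    def test_rotation_approximately_conserves_the_mean(self, rng):
        """Bilinear resampling keeps the window mean within ~1% on smooth data."""
        y, x = np.mgrid[0:29, 0:29]
        buf = 10.0 + np.sin(x / 5.0) + np.cos(y / 7.0)
        for ang in (30.0, 137.0, 261.0):
            out = rotate_window(buf, ang, 7)
            assert np.nanmean(out) == pytest.approx(buf[7:22, 7:22].mean(), rel=0.01)


class TestComposite:
    def test_copies_average_to_themselves(self, rng):
        w = rng.normal(size=(15, 15))
        comp = composite([w, w.copy(), w.copy()])
        assert np.allclose(comp.mean_window, w)
        assert np.all(comp.count_window == 3)

    def test_two_windows_average(self):
        comp = composite([np.full((5, 5), 1.0), np.full((5, 5), 3.0)])
        assert np.allclose(comp.mean_window, 2.0)

    def test_disjoint_valid_cells_union(self):
        a = np.full((3, 3), np.nan)
        b = np.full((3, 3), np.nan)
        a[0, 0] = 1.0
        b[2, 2] = 5.0
        comp = composite([a, b])
        assert comp.count_window[0, 0] == 1
        assert comp.count_window[2, 2] == 1
        assert comp.count_window[1, 1] == 0
        assert np.isnan(comp.mean_window[1, 1])

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            composite([])


class TestEnhancement:
    def test_uniform_composite_is_zero(self):
        comp = RotatedComposite(np.full((15, 15), 2.0), np.ones((15, 15)))
        res = enhancement(comp)
        assert res.enhancement_pct == pytest.approx(0.0)
        # degenerate argmax ties break toward the window center
        assert res.peak_offset == (0, 0)
        assert res.displacement_km == 0.0

    def test_formula_identity_17_9_pct(self):
        vals = np.full((15, 15), 1.0)
        vals[7, 11] = 1.179
        comp = RotatedComposite(vals, np.ones((15, 15)))
        res = enhancement(comp)
        assert res.upwind_edge_mean == pytest.approx(1.0)
        assert res.enhancement_pct == pytest.approx(17.9, abs=1e-9)
        assert res.peak_offset == (4, 0)
        assert res.displacement_km == pytest.approx(4.0)

    def test_nonnegative_on_random_composites(self, rng):
        for _ in range(200):
            vals = rng.lognormal(0, 0.5, size=(9, 9))
            comp = RotatedComposite(vals, np.ones((9, 9)))
            assert enhancement(comp).enhancement_pct >= 0.0

    def test_edge_entirely_invalid_raises(self):
        vals = np.ones((5, 5))
        counts = np.ones((5, 5))
        counts[:, 0] = 0
        with pytest.raises(ValueError, match="edge"):
            enhancement(RotatedComposite(vals, counts))

    def test_nonpositive_edge_mean_raises(self):
        vals = np.zeros((5, 5))
        with pytest.raises(ValueError, match="edge"):
            enhancement(RotatedComposite(vals, np.ones((5, 5))))

    def test_configurable_edge_cells(self):
        vals = np.ones((5, 5))
        vals[0, 0] = 3.0  # excluded from a reduced edge set
        comp = RotatedComposite(vals, np.ones((5, 5)))
        res = enhancement(comp, edge_cells=[(1, 0), (2, 0), (3, 0)])
        assert res.upwind_edge_mean == pytest.approx(1.0)


class TestStratified:
    def test_single_label_equals_unstratified(self, rng):
        windows = {f"f{i}": rng.lognormal(1, 0.2, size=(15, 15)) for i in range(6)}
        labels = {k: "all" for k in windows}
        strat = stratified_enhancement(windows, labels)
        pooled = enhancement(composite(list(windows.values())))
        assert strat["all"].enhancement_pct == pytest.approx(pooled.enhancement_pct)

    def test_labels_partition_facilities(self, rng):
        windows = {f"f{i}": rng.lognormal(1, 0.2, size=(7, 7)) for i in range(10)}
        labels = {k: ("a" if i < 4 else "b") for i, k in enumerate(windows)}
        strat = stratified_enhancement(windows, labels)
        assert set(strat) == {"a", "b"}

    def test_unlabeled_facility_raises(self, rng):
        windows = {"f0": rng.normal(size=(7, 7)), "f1": rng.normal(size=(7, 7))}
        with pytest.raises(ValueError):
            stratified_enhancement(windows, {"f0": "a"})


class TestRotationDistinguishesWindRegimes:
    """A fixed off-center plume composited under random wind directions is
    radially symmetric; under a fixed wind it is not."""

    def _plume_window(self, direction_deg):
        # plume 4 cells from center along `direction_deg` in geographic frame
        buf = np.zeros((29, 29))
        dx = 4 * np.cos(np.radians(direction_deg))
        dy = 4 * np.sin(np.radians(direction_deg))
        y, x = np.mgrid[0:29, 0:29]
        buf += np.exp(-((x - (14 + dx)) ** 2 + (y - (14 + dy)) ** 2) / 4.0)
        return buf

    def test_random_directions_symmetric_fixed_not(self, rng):
        # random-wind composite WITHOUT rotation (plume direction random,
        # windows left in the geographic frame)
        random_comp = composite(
            [self._plume_window(d)[7:22, 7:22] for d in rng.uniform(0, 360, 500)]
        )
        # fixed-wind: every day the plume sits east; rotation is identity
        fixed_comp = composite([self._plume_window(0.0)[7:22, 7:22]] * 60)
        sym = radial_asymmetry(random_comp.mean_window)
        asym = radial_asymmetry(fixed_comp.mean_window)
        assert sym < 0.5
        assert asym > 1.0

    def test_rotation_restores_the_offcenter_peak(self, rng):
        # rotating by the known direction must put every plume downwind (+x)
        rotated = []
        for d in rng.uniform(0, 360, 40):
            rotated.append(rotate_window(self._plume_window(d), d, 7))
        comp = composite(rotated)
        res = enhancement(comp)
        assert res.peak_offset[0] == 4
        assert abs(res.peak_offset[1]) <= 1


def test_composite_netcdf_roundtrip(tmp_path, rng):
    from plumewake.composite import read_composite, write_composite

    w = rng.lognormal(0, 0.3, size=(15, 15))
    w[0, 0] = np.nan
    comp = composite([w])
    write_composite(comp, tmp_path / "comp.nc")
    back = read_composite(tmp_path / "comp.nc")
    assert back.radius == comp.radius
    assert np.allclose(back.mean_window, comp.mean_window, equal_nan=True)
    assert np.array_equal(back.count_window, comp.count_window)


class TestPlumeCompositeModel:
    def test_fit_on_constructed_single_facility(self):
        # one facility, constant eastward wind, plume 4 cells east
        g = GridSpec(0, 0, 0.01, 60, 60)
        fac_lon, fac_lat = 0.305, 0.305
        iy, ix = g.cell_of(fac_lon, fac_lat)
        vals = np.ones(g.shape)
        y, x = np.mgrid[0 : g.n_lat, 0 : g.n_lon]
        vals += 0.5 * np.exp(-((x - (ix + 4)) ** 2 + (y - iy) ** 2) / 8.0)
        fields = [RasterField(g, vals)] * 3
        import pandas as pd

        facilities = pd.DataFrame({"id": ["w1"], "lon": [fac_lon], "lat": [fac_lat]})
        winds = constant_winds(5, 0, n_days=3, n=8)
        res = PlumeCompositeModel(fields, facilities, winds).fit()
        assert res.enhancement_.peak_offset[0] == 4
        assert res.displacement_km == pytest.approx(4.0)
        assert res.enhancement_pct > 10
        assert "enhancement" in res.summary()

    def test_mismatched_days_raise(self):
        import pandas as pd

        g = GridSpec(0, 0, 0.01, 30, 30)
        fields = [RasterField(g, np.ones(g.shape))]
        facilities = pd.DataFrame({"id": ["w1"], "lon": [0.15], "lat": [0.15]})
        with pytest.raises(ValueError):
            PlumeCompositeModel(fields, facilities, constant_winds(1, 0, n_days=2))
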