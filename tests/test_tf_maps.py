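"""Normalization, time rescaling and Gaussian smoothing of TF maps."""

import numpy as np
import pytest

from swdmaps.spectral import TFGrid, TFMap, default_grid
from swdmaps.tf_maps import (DegenerateBaselineError, normalize_map, rescale_time,
                             smooth_map)


def _map(values, t0=0.0, dt=0.1, kind="power"):
    values = np.asarray(values, dtype=float)
    grid = TFGrid(times=t0 + dt * np.arange(values.shape[0]),
                  freqs=4.0 + 0.1 * np.arange(values.shape[1]))
    return TFMap(grid=grid, values=values, kind=kind)


class TestNormalizeMap:
    def test_known_baseline_mean_and_sd(self):
        # baseline bins [1, 3, 5] per frequency: mean 3, sample SD 2; ictal 7 -> z = 2
        vals = np.tile(np.array([1.0, 3.0, 5.0, 7.0])[:, None], (1, 5))
        m = _map(vals)
        z = normalize_map(m, baseline_interval=(0.0, 0.25))
        np.testing.assert_allclose(z.values[3], 2.0, atol=1e-12)
        assert z.kind == "z-power"
        np.testing.assert_array_equal(z.baseline_bins, [0, 1, 2])

    def test_constant_baseline_is_degenerate(self):
        m = _map(np.ones((10, 4)))
        with pytest.raises(DegenerateBaselineError, match="Hz"):
            normalize_map(m, (0.0, 0.5))

    def test_matches_brute_force_oracle(self, rng):
        vals = rng.random((40, 17))
        m = _map(vals)
        z = normalize_map(m, (0.0, 0.95))
        # independent per-frequency z-score computation
        expected = np.empty_like(vals)
        for j in range(vals.shape[1]):
            base = vals[:10, j]
            expected[:, j] = (vals[:, j] - base.mean()) / base.std(ddof=1)
        np.testing.assert_allclose(z.values, expected, atol=1e-10)

    def test_baseline_bins_standardized_after_normalization(self, rng):
        m = _map(rng.random((30, 6)))
        z = normalize_map(m, (0.0, 0.95))
        base = z.values[z.baseline_bins]
        np.testing.assert_allclose(base.mean(axis=0), 0.0, atol=1e-12)
        np.testing.assert_allclose(base.std(axis=0, ddof=1), 1.0, atol=1e-12)

    def test_too_few_baseline_bins_rejected(self, rng):
        m = _map(rng.random((10, 3)))
        with pytest.raises(ValueError, match=">= 2"):
            normalize_map(m, (0.0, 0.05))


class TestRescaleTime:
    def test_identity_when_already_on_target_axis(self, rng):
        onset, offset, n = 10.0, 20.0, 121
        u = np.linspace(-0.1, 1.1, n)
        grid = TFGrid(times=onset + u * (offset - onset), freqs=np.arange(4.0, 5.0, 0.1))
        m = TFMap(grid=grid, values=rng.random((n, grid.freqs.size)), kind="power")
        out = rescale_time(m, onset, offset, n)
        np.testing.assert_allclose(out.values, m.values, atol=1e-12)
        assert out.rescaled

    def test_events_of_different_lengths_share_output_shape(self, rng):
        for dur in (10.0, 30.0):
            onset = 0.1 * dur + 1.0
            grid = default_grid(0.0, onset + 1.2 * dur + 1.0)
            m = TFMap(grid=grid, values=rng.random(grid.shape), kind="power")
            out = rescale_time(m, onset, onset + dur, 121)
            assert out.values.shape == (121, grid.freqs.size)
            np.testing.assert_allclose(out.grid.times, np.linspace(-0.1, 1.1, 121))

    def test_linear_map_matches_closed_form(self):
        # values linear in time are preserved exactly by linear interpolation
        grid = default_grid(0.0, 40.0)
        slope, icept = 2.5, -3.0
        vals = (slope * grid.times + icept)[:, None] * np.ones((1, grid.freqs.size))
        m = TFMap(grid=grid, values=vals, kind="z-power")
        onset, offset = 5.0, 35.0
        out = rescale_time(m, onset, offset, 61)
        expected = slope * (onset + out.grid.times * 30.0) + icept
        np.testing.assert_allclose(
            out.values, np.tile(expected[:, None], (1, grid.freqs.size)), atol=1e-10)

    def test_insufficient_coverage_rejected(self, rng):
        grid = default_grid(0.0, 10.0)
        m = TFMap(grid=grid, values=rng.random(grid.shape), kind="power")
        with pytest.raises(ValueError, match="cover"):
            rescale_time(m, 1.0, 11.0, 61)


class TestSmoothMap:
    def _rescaled(self, values):
        n = values.shape[0]
        grid = TFGrid(times=np.linspace(-0.1, 1.1, n),
                      freqs=4.0 + 0.1 * np.arange(values.shape[1]))
        return TFMap(grid=grid, values=values, kind="z-power", rescaled=True)

    def test_constant_map_unchanged(self):
        m = self._rescaled(np.full((121, 161), 3.7))
        out = smooth_map(m)
        np.testing.assert_allclose(out.values, 3.7, atol=1e-10)

    def test_impulse_response_has_nominal_fwhm(self):
        vals = np.zeros((121, 161))
        vals[60, 80] = 1.0
        out = smooth_map(self._rescaled(vals))

        def measured_fwhm(profile):
            half = profile.max() / 2
            above = np.flatnonzero(profile >= half)
            return above[-1] - above[0] + 1

        # nominal FWHMs: 0.05 / 0.01 = 5 time bins, 5 Hz / 0.1 Hz = 50 freq bins
        assert measured_fwhm(out.values[:, 80]) == pytest.approx(5, abs=1)
        assert measured_fwhm(out.values[60, :]) == pytest.approx(50, abs=2.5)

    def test_interior_impulse_mass_conserved(self):
        # grid wide enough that the truncated kernel support (4 SD) is interior
        vals = np.zeros((121, 361))
        vals[60, 180] = 1.0
        out = smooth_map(self._rescaled(vals))
        assert out.values.sum() == pytest.approx(1.0, abs=1e-8)

    def test_positivity_preserved(self, rng):
        m = self._rescaled(rng.random((61, 41)))
        assert smooth_map(m).values.min() >= 0

    def test_requires_rescaled_map_and_positive_fwhm(self, rng):
        m = _map(rng.random((61, 41)))
        with pytest.raises(ValueError, match="rescaled"):
            smooth_map(m)
        with pytest.raises(ValueError, match="positive"):
            smooth_map(self._rescaled(rng.random((61, 41))), fwhm_time_fraction=0.0)


class TestNormalizeRescaleCommutation:
    def test_order_of_normalize_and_rescale_commutes(self):
        # smooth map so linear interpolation is nearly exact; matched baselines
        grid = default_grid(0.0, 36.0)
        t = grid.times[:, None]
        f = grid.freqs[None, :]
        vals = 5.0 + np.sin(0.8 * t) * (1.0 + 0.1 * f) + 0.02 * f * np.cos(0.5 * t)
        m = TFMap(grid=grid, values=vals, kind="power")
        onset, offset = 5.0, 30.0
        # 301 bins over [-0.1, 1.1] of a 25 s seizure puts every target time on
        # the 0.1 s source grid, so both orders use identical baseline samples
        n = 301
        a = rescale_time(normalize_map(m, (onset - 2.51, onset + 0.01)), onset, offset, n)
        b = normalize_map(rescale_time(m, onset, offset, n), (-0.1004, 0.0004))
        np.testing.assert_allclose(a.values, b.values, atol=1e-8)
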