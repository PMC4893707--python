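"""Synthetic session generator: waveform morphology, calibration, effects."""

import numpy as np
import pytest
from scipy import signal as sps

from swdmaps.spectral import default_grid, sliding_welch_coherence
from swdmaps.synth_lfp import (EffectSpec, PlacementError, SessionConfig,
                               default_layout, generate_event_window,
                               generate_session, one_over_f_noise, swd_waveform)

from conftest import fast_config


class TestSWDWaveform:
    def test_dominant_peak_at_fundamental(self):
        fs = 500.0
        x = swd_waveform(25.0, 7.0, fs=fs, seed=0)
        f, p = sps.periodogram(x, fs=fs)
        assert f[np.argmax(p)] == pytest.approx(7.0, abs=0.15)

    def test_pure_fundamental_has_no_harmonic_power(self):
        fs = 500.0
        x = swd_waveform(20.0, 7.0, harmonic_amps=(1.0,), fs=fs, seed=0)
        f, p = sps.periodogram(x, fs=fs)
        band = lambda lo, hi: p[(f >= lo) & (f <= hi)].sum()
        # residual 2f0 content is jitter/AM sideband leakage only
        assert band(13, 15) < 0.05 * band(6, 8)

    def test_harmonic_rich_waveform_is_spiky(self):
        x = swd_waveform(10.0, 7.0, fs=500.0, seed=1)
        # one sharp positive peak per cycle: crest factor well above sinusoid's sqrt(2)
        assert x.max() / np.sqrt(np.mean(x**2)) > 1.8

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            swd_waveform(0.0, 7.0)
        with pytest.raises(ValueError):
            swd_waveform(10.0, -1.0)


class TestGenerateSession:
    def test_zero_rate_gives_background_only(self):
        rec, events = generate_session(fast_config(swd_rate_per_h=0.0))
        assert events == []
        assert rec.samples.shape == (10, int(300 * 250))

    def test_same_seed_is_bit_identical(self):
        cfg = fast_config(seed=5)
        rec1, ev1 = generate_session(cfg)
        rec2, ev2 = generate_session(cfg)
        np.testing.assert_array_equal(rec1.samples, rec2.samples)
        assert ev1 == ev2

    def test_different_seeds_differ(self):
        rec1, _ = generate_session(fast_config(seed=1))
        rec2, _ = generate_session(fast_config(seed=2))
        assert not np.array_equal(rec1.samples, rec2.samples)

    def test_durations_respect_truncation_bounds(self):
        durs = []
        for s in range(6):
            _, evs = generate_session(fast_config(duration_s=1200.0, seed=s, fs=100.0))
            durs.extend(e.duration_s for e in evs)
        durs = np.asarray(durs)
        assert durs.min() >= 5.0 and durs.max() <= 60.0
        assert durs.mean() == pytest.approx(24.8, abs=3 * 2.7 / np.sqrt(durs.size))

    def test_event_count_is_poisson_consistent(self):
        # dispersion index (var/mean) of per-session counts ~ 1
        counts = [
            len(generate_session(fast_config(duration_s=600.0, seed=s, fs=100.0))[1])
            for s in range(40)
        ]
        counts = np.asarray(counts, dtype=float)
        index = counts.var(ddof=1) / counts.mean()
        se = np.sqrt(2.0 / (len(counts) - 1))
        assert abs(index - 1.0) < 3 * se

    def test_impossible_rate_raises_placement_error(self):
        with pytest.raises(PlacementError):
            generate_session(fast_config(duration_s=120.0, swd_rate_per_h=3000.0, seed=0))

    def test_layout_must_be_hemisphere_balanced(self):
        bad = default_layout()[:9]
        with pytest.raises(ValueError, match="balanced"):
            SessionConfig(layout=bad)


class TestEffects:
    def test_power_scale_reduces_target_band_power(self):
        # oracle: direct periodogram of the ictal segments, target vs untouched
        ratios = []
        for s in range(8):
            rec, ev = generate_event_window(
                fast_config(seed=100 + s), duration_s=25.0,
                effect=EffectSpec(power_scale=0.36),
            )
            i0, i1 = int(ev.onset_s * rec.fs), int(ev.offset_s * rec.fs)

            def band_power(label):
                f, p = sps.periodogram(rec.trace(label)[i0:i1], fs=rec.fs)
                return p[(f >= 6) & (f <= 8)].sum()

            ratios.append(
                np.mean([band_power("L2"), band_power("L3")])
                / np.mean([band_power("R2"), band_power("R3")])
            )
        assert np.mean(ratios) == pytest.approx(0.36, rel=0.10)

    def test_full_coupling_gives_unit_ictal_coherence(self):
        rec, ev = generate_event_window(fast_config(seed=7, coupling=1.0), duration_s=20.0)
        grid = default_grid(ev.onset_s + 1, ev.offset_s - 1)
        c = sliding_welch_coherence(rec.trace("L2"), rec.trace("L3"), rec.fs, grid)
        swd_band = (grid.freqs >= 6) & (grid.freqs <= 8)
        assert c.values[:, swd_band].mean() > 0.95

    def test_coherence_drop_decorrelates_target_channels(self):
        def band_coherence(effect):
            rec, ev = generate_event_window(
                fast_config(seed=7, coupling=0.0), duration_s=20.0, effect=effect)
            grid = default_grid(ev.onset_s + 1, ev.offset_s - 1)
            c = sliding_welch_coherence(rec.trace("L2"), rec.trace("L3"), rec.fs, grid)
            return c.values[:, (grid.freqs >= 6) & (grid.freqs <= 8)].mean()

        intact = band_coherence(None)
        dropped = band_coherence(EffectSpec(coherence_drop=1.0, target_channels=("L2", "L3")))
        assert intact > 0.9
        assert dropped < 0.5  # falls toward the independent-estimate floor

    def test_effect_spec_validation(self):
        with pytest.raises(ValueError):
            EffectSpec(power_scale=-0.1)
        with pytest.raises(ValueError):
            EffectSpec(coherence_drop=1.5)


class TestBackgroundNoise:
    def test_one_over_f_slope(self, rng):
        fs = 250.0
        x = one_over_f_noise(int(600 * fs), fs, exponent=1.0, rng=rng)
        f, p = sps.welch(x, fs=fs, nperseg=4096)
        sel = (f >= 1.0) & (f <= 60.0)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.15)

    def test_unit_rms(self, rng):
        x = one_over_f_noise(100_000, 250.0, 1.0, rng)
        assert np.sqrt((x**2).mean()) == pytest.approx(1.0, rel=1e-9)
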