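"""Baseline normalization, seizure time rescaling and map smoothing.

Maps are z-scored per frequency against the pre-seizure baseline (the 10%
pre-onset margin): subtract the baseline mean, divide by the baseline sample
SD.  The time axis is then linearly rescaled onto a common seizure axis with
onset at 0 and offset at 1 (map span [-0.1, 1.1], 121 bins by default) so
seizures of different lengths can be averaged and compared pixel-wise.
Before inference, maps are smoothed with a separable Gaussian kernel: FWHM
5% of the seizure duration in time and 5 Hz in frequency.  The kernel is
truncated at +/-4 SD and renormalized at the edges (mass-preserving), which
avoids contaminating border bins with implicit zero padding.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

from .spectral import TFGrid, TFMap

_FWHM_TO_SD = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class DegenerateBaselineError(ValueError):
    """A frequency row has zero variance in the baseline interval."""


def normalize_map(m: TFMap, baseline_interval: tuple[float, float]) -> TFMap:
    """Per-frequency z-scoring against the baseline time bins.

    For each frequency, the baseline mean is subtracted from the whole map row
    and the row is divided by the baseline sample SD.
    """
    t_lo, t_hi = baseline_interval
    bins = np.flatnonzero((m.grid.times >= t_lo) & (m.grid.times <= t_hi))
    if bins.size < 2:
        raise ValueError(
            f"baseline interval ({t_lo}, {t_hi}) covers {bins.size} time bins; need >= 2"
        )
    base = m.values[bins]
    mu = base.mean(axis=0)
    sd = base.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        raise DegenerateBaselineError(
            "zero baseline SD at frequencies "
            + ", ".join(f"{m.grid.freqs[i]:.1f} Hz" for i in bad[:5])
            + ("..." if bad.size > 5 else "")
        )
    z = (m.values - mu) / sd
    kind = {"power": "z-power", "coherence": "z-coherence"}.get(m.kind, m.kind)
    return m.copy_with(values=z, kind=kind, baseline_bins=bins)


def rescale_time(m: TFMap, onset: float, offset: float, n_bins: int = 121) -> TFMap:
    """Linearly map seizure time onto the common axis [-0.1, 1.1] (onset=0, offset=1).

    Each frequency row is linearly interpolated at the target times; the
    result of every event shares an identical axis so maps can be stacked.
    """
    if not offset > onset:
        raise ValueError("offset must exceed onset")
    dur = offset - onset
    u = np.linspace(-0.1, 1.1, n_bins)
    t_target = onset + u * dur
    t = m.grid.times
    tol = 0.5 * (t[1] - t[0]) if t.size > 1 else 0.0
    if t_target[0] < t[0] - tol or t_target[-1] > t[-1] + tol:
        raise ValueError(
            f"map times [{t[0]:.3f}, {t[-1]:.3f}] do not cover the analysis window "
            f"[{t_target[0]:.3f}, {t_target[-1]:.3f}]"
        )
    t_target = np.clip(t_target, t[0], t[-1])
    out = np.empty((n_bins, m.grid.freqs.size))
    for j in range(m.grid.freqs.size):
        out[:, j] = np.interp(t_target, t, m.values[:, j])
    grid = TFGrid(times=u, freqs=m.grid.freqs, window_s=m.grid.window_s)
    meta = dict(m.meta, onset_s=onset, offset_s=offset)
    return m.copy_with(values=out, grid=grid, rescaled=True, baseline_bins=None, meta=meta)


def _renormalized_gaussian(values: np.ndarray, sigmas: tuple[float, float]) -> np.ndarray:
    sm = ndimage.gaussian_filter(values, sigma=sigmas, mode="constant", cval=0.0, truncate=4.0)
    norm = ndimage.gaussian_filter(np.ones_like(values), sigma=sigmas, mode="constant",
                                   cval=0.0, truncate=4.0)
    return sm / norm


def smooth_map(m: TFMap, fwhm_time_fraction: float = 0.05, fwhm_freq_hz: float = 5.0) -> TFMap:
    """Separable Gaussian smoothing on a rescaled map.

    FWHMs: ``fwhm_time_fraction`` of the unit seizure axis in time (default
    5% of seizure duration) and ``fwhm_freq_hz`` in frequency (default 5 Hz).
    """
    if fwhm_time_fraction <= 0 or fwhm_freq_hz <= 0:
        raise ValueError("FWHMs must be positive")
    if not m.rescaled:
        raise ValueError("smooth_map expects a time-rescaled map (unit seizure axis)")
    fwhm_t_bins = fwhm_time_fraction / m.grid.dt
    fwhm_f_bins = fwhm_freq_hz / m.grid.df
    sig = (fwhm_t_bins * _FWHM_TO_SD, fwhm_f_bins * _FWHM_TO_SD)
    out = _renormalized_gaussian(m.values, sig)
    meta = dict(m.meta, fwhm_t_bins=fwhm_t_bins, fwhm_f_bins=fwhm_f_bins)
    return m.copy_with(values=out, meta=meta)
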