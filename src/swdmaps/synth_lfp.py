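"""Synthetic GAERS-like multi-channel LFP sessions with ground-truth SWDs.

The generator emulates the statistical signature of absence-epilepsy
recordings rather than their biophysics:

* background: Gaussian 1/f^beta noise per channel, with a shared component
  across channels controlling baseline inter-channel coherence;
* seizures: ~7 Hz spike-wave bursts built as a phase-aligned harmonic stack
  (one sharp peak per cycle) with Ornstein-Uhlenbeck phase jitter and mild
  amplitude modulation, inserted on all channels as a common waveform so that
  ictal inter-channel coherence is high;
* events: Poisson process in time (default 62.2/h) with truncated-normal
  durations (default 24.8 +/- 2.7 s, truncated to [5, 60] s), placed without
  overlap of their 10%-margin analysis windows;
* treatment effect: on the target channels only, the SWD component power is
  scaled by ``power_scale`` and a fraction ``coherence_drop`` of its variance
  is replaced by an independently jittered copy, reducing inter-channel
  coherence without touching the background (interictal) signal.

Seizure amplitude is calibrated so the broadband ictal/interictal power ratio
is ~10; because SWD power concentrates near the 7 Hz fundamental while the
1/f background spreads over the whole band, the in-band (6-8 Hz) SNR is of
order 100, as in real recordings where seizures dwarf the background.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import Channel, Recording
from .swd_events import SWDEvent


class PlacementError(RuntimeError):
    """Events could not be placed without overlap within the retry budget."""


_DEFAULT_AP = (3.0, 1.0, -1.0, -3.0, -5.0)  # mm from bregma


def default_layout(n_per_row: int = 5, ml_mm: float = 4.5) -> tuple[Channel, ...]:
    """Two symmetrical rows of electrodes at AP +3..-5 mm, ML +/-4.5 mm.

    Coordinates are chosen so the four transection planes (+2, 0, -2, -4 mm)
    fall midway between adjacent left-row electrodes.
    """
    ap = _DEFAULT_AP if n_per_row == 5 else tuple(
        np.linspace(3.0, -5.0, n_per_row)
    )
    left = tuple(Channel(f"L{i+1}", "left", ap[i], -ml_mm) for i in range(n_per_row))
    right = tuple(Channel(f"R{i+1}", "right", ap[i], ml_mm) for i in range(n_per_row))
    return left + right


@dataclass(frozen=True)
class SessionConfig:
    """Parameters of one simulated recording session."""

    fs: float = 5000.0
    duration_s: float = 3600.0
    layout: tuple[Channel, ...] = field(default_factory=default_layout)
    swd_rate_per_h: float = 62.2
    swd_duration_mean_s: float = 24.8
    swd_duration_sd_s: float = 2.7
    swd_duration_bounds_s: tuple[float, float] = (5.0, 60.0)
    f0_hz: float = 7.0
    harmonic_amps: tuple[float, ...] = (1.0, 0.6, 0.35, 0.2, 0.1)
    background_exponent: float = 1.0
    background_rms_uv: float = 50.0
    coupling: float = 0.6
    ictal_power_ratio: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.swd_rate_per_h < 0:
            raise ValueError("swd_rate_per_h must be non-negative")
        if not 4.0 <= self.f0_hz <= 20.0:
            raise ValueError("f0_hz must lie in [4, 20] so the fundamental is on the analysis grid")
        if not 0.0 <= self.coupling <= 1.0:
            raise ValueError("coupling must lie in [0, 1]")
        n_left = sum(c.hemisphere == "left" for c in self.layout)
        n_right = sum(c.hemisphere == "right" for c in self.layout)
        if n_left != n_right:
            raise ValueError(f"layout must be hemisphere-balanced, got {n_left} left / {n_right} right")

    @property
    def n_channels(self) -> int:
        return len(self.layout)


@dataclass(frozen=True)
class EffectSpec:
    """Treatment signature applied to a channel subset (default: left hemisphere).

    power_scale multiplies the SWD component power (amplitude^2); the 6-8 Hz
    band carries most of it since the fundamental sits at 7 Hz.
    coherence_drop is the fraction of SWD variance replaced per channel by an
    independently phase-jittered copy.
    """

    target_channels: tuple[str, ...] | None = None
    power_scale: float = 1.0
    coherence_drop: float = 0.0
    onset_session: int = 0

    def __post_init__(self) -> None:
        if self.power_scale < 0:
            raise ValueError("power_scale must be non-negative")
        if not 0.0 <= self.coherence_drop <= 1.0:
            raise ValueError("coherence_drop must lie in [0, 1]")

    def resolve_targets(self, layout: Sequence[Channel]) -> tuple[str, ...]:
        if self.target_channels is not None:
            return tuple(self.target_channels)
        return tuple(c.label for c in layout if c.hemisphere == "left")


# ---------------------------------------------------------------------------
# Waveforms and noise
# ---------------------------------------------------------------------------

def _ou_phase_jitter(n: int, fs: float, sd_rad: float, tau_s: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Stationary Ornstein-Uhlenbeck phase noise (AR(1) at the sample rate)."""
    if sd_rad == 0:
        return np.zeros(n)
    a = np.exp(-1.0 / (tau_s * fs))
    innov_sd = sd_rad * np.sqrt(1.0 - a * a)
    w = rng.standard_normal(n) * innov_sd
    w[0] = rng.standard_normal() * sd_rad
    phi = sps.lfilter([1.0], [1.0, -a], w)
    # pin both endpoints to zero (bridge) so the accumulated phase over the
    # burst is exactly 2 pi f0 T and the cycle count is deterministic
    phi -= phi[0] + (phi[-1] - phi[0]) * np.arange(n) / max(n - 1, 1)
    return phi


def swd_waveform(
    duration_s: float,
    f0: float = 7.0,
    harmonic_amps: Sequence[float] = (1.0, 0.6, 0.35, 0.2, 0.1),
    fs: float = 5000.0,
    seed: int | np.random.Generator | None = 0,
    phase_jitter_sd: float = 1.0,
    phase_jitter_tau_s: float = 0.3,
    edge_s: float = 0.1,
    am_depth: float = 0.1,
    phase_offset_rad: float = 0.0,
) -> np.ndarray:
    """One ictal spike-wave burst, unit RMS.

    A stack of cosine harmonics of f0 with a common (jittered) phase: the
    aligned harmonics produce one sharp positive peak per cycle, giving the
    spike-and-wave morphology and a harmonic-rich spectrum dominated by f0.
    With only the fundamental the output degenerates to a (jittered) sinusoid.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    if f0 <= 0:
        raise ValueError("f0 must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    # +pi offset puts the per-cycle peaks mid-cycle, clear of the edge ramps,
    # so a burst of duration d carries round(d * f0) spikes
    phase = (2 * np.pi * f0 * t + np.pi + phase_offset_rad
             + _ou_phase_jitter(n, fs, phase_jitter_sd, phase_jitter_tau_s, rng))
    x = np.zeros(n)
    for k, a in enumerate(harmonic_amps, start=1):
        if a != 0:
            x += a * np.cos(k * phase)
    # slow multiplicative amplitude modulation
    if am_depth > 0:
        slow = _ou_phase_jitter(n, fs, 1.0, 1.0, rng)
        x *= np.clip(1.0 + am_depth * slow, 0.2, None)
    # raised-cosine on/off ramps
    ne = min(int(round(edge_s * fs)), n // 2)
    if ne > 0:
        ramp = 0.5 * (1 - np.cos(np.pi * np.arange(ne) / ne))
        x[:ne] *= ramp
        x[-ne:] *= ramp[::-1]
    rms = np.sqrt(np.mean(x * x))
    return x / rms if rms > 0 else x


def one_over_f_noise(n: int, fs: float, exponent: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectrum ~ 1/f^exponent."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(f)
    nz = f > 0
    shaping[nz] = f[nz] ** (-exponent / 2.0)
    # flatten below 0.5 Hz to keep variance finite and drifts bounded
    low = (f > 0) & (f < 0.5)
    shaping[low] = 0.5 ** (-exponent / 2.0)
    shaping[0] = 0.0
    x = np.fft.irfft(spec * shaping, n=n)
    return x / np.sqrt(np.mean(x * x))


# ---------------------------------------------------------------------------
# Event placement
# ---------------------------------------------------------------------------

def _draw_durations(n: int, cfg: SessionConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.swd_duration_bounds_s
    out = np.empty(n)
    filled = 0
    for _ in range(1000):
        if filled >= n:
            break
        draw = rng.normal(cfg.swd_duration_mean_s, cfg.swd_duration_sd_s, size=2 * (n - filled) + 8)
        keep = draw[(draw >= lo) & (draw <= hi)][: n - filled]
        out[filled: filled + keep.size] = keep
        filled += keep.size
    if filled < n:
        raise RuntimeError("truncated-normal rejection sampling failed to converge")
    return out


def _place_events(
    durations: np.ndarray,
    session_s: float,
    rng: np.random.Generator,
    gap_s: float = 4.0,
    edge_pad_s: tuple[float, float] = (6.5, 2.5),
) -> list[SWDEvent]:
    """Place events at random so that the 10%-margin analysis windows (plus
    the spectral-window edge padding) stay inside the session and are
    separated by >= gap_s.

    The free time left after reserving every event block is partitioned into
    random inter-event gaps (normalized exponentials), i.e. event positions
    are uniform order statistics conditioned on non-overlap; this stays exact
    even at high occupancy where rejection sampling would jam.
    """
    n = durations.size
    if n == 0:
        return []
    blocks = 1.2 * durations + gap_s          # duration + both margins + spacing
    free = session_s - edge_pad_s[0] - edge_pad_s[1] - float(blocks.sum()) + gap_s
    if free < 0:
        raise PlacementError(
            f"cannot place {n} events of ~{np.mean(durations):.0f} s "
            f"in {session_s:.0f} s without overlap"
        )
    gaps = rng.exponential(size=n + 1)
    gaps = gaps / gaps.sum() * free
    events: list[SWDEvent] = []
    t = edge_pad_s[0] + gaps[0]
    for d, g in zip(durations, gaps[1:]):
        m = 0.1 * d
        onset = t + m
        events.append(SWDEvent(onset, onset + d))
        t += 1.2 * d + gap_s + g
    return events


# ---------------------------------------------------------------------------
# Session synthesis
# ---------------------------------------------------------------------------

def _insert_swd(
    samples: np.ndarray,
    cfg: SessionConfig,
    event: SWDEvent,
    event_rng: np.random.Generator,
    targets: frozenset[str],
    power_scale: float,
    coherence_drop: float,
) -> None:
    fs = cfg.fs
    i0 = int(round(event.onset_s * fs))
    n = int(round(event.duration_s * fs))
    n = min(n, samples.shape[1] - i0)
    amp = cfg.background_rms_uv * np.sqrt(max(cfg.ictal_power_ratio - 1.0, 0.0))
    shared = swd_waveform(n / fs, cfg.f0_hz, cfg.harmonic_amps, fs, seed=event_rng)
    w_shared = np.sqrt(1.0 - coherence_drop)
    w_indep = np.sqrt(coherence_drop)
    for ci, ch in enumerate(cfg.layout):
        if ch.label in targets:
            comp = shared
            if coherence_drop > 0:
                # a random global phase makes the replacement statistically
                # independent of the shared burst (no power-inflating cross term)
                indep = swd_waveform(n / fs, cfg.f0_hz, cfg.harmonic_amps, fs,
                                     seed=event_rng,
                                     phase_offset_rad=event_rng.uniform(0, 2 * np.pi))
                comp = w_shared * shared + w_indep * indep
            samples[ci, i0: i0 + n] += amp * np.sqrt(power_scale) * comp[:n]
        else:
            samples[ci, i0: i0 + n] += amp * shared[:n]


def _background(cfg: SessionConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Channels x samples 1/f^beta background with a shared coherent component.

    coupling is the shared-variance fraction; baseline magnitude-squared
    coherence between channels is coupling^2.
    """
    w_s = np.sqrt(cfg.coupling)
    w_i = np.sqrt(1.0 - cfg.coupling)
    shared = one_over_f_noise(n, cfg.fs, cfg.background_exponent, rng) if cfg.coupling > 0 else 0.0
    out = np.empty((cfg.n_channels, n), dtype=np.float32)
    for ci in range(cfg.n_channels):
        indep = one_over_f_noise(n, cfg.fs, cfg.background_exponent, rng)
        out[ci] = cfg.background_rms_uv * (w_s * shared + w_i * indep)
    return out


def generate_session(
    config: SessionConfig,
    effect: EffectSpec | None = None,
) -> tuple[Recording, list[SWDEvent]]:
    """Simulate one session; returns the Recording and the exact ground-truth events.

    Bit-identical output for identical (config, effect): all randomness comes
    from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n_events = rng.poisson(config.swd_rate_per_h * config.duration_s / 3600.0)
    durations = _draw_durations(n_events, config, rng) if n_events else np.empty(0)
    events = _place_events(durations, config.duration_s, rng) if n_events else []

    n = int(round(config.duration_s * config.fs))
    samples = _background(config, n, rng)

    if effect is not None:
        targets = frozenset(effect.resolve_targets(config.layout))
        power_scale, coherence_drop = effect.power_scale, effect.coherence_drop
    else:
        targets, power_scale, coherence_drop = frozenset(), 1.0, 0.0
    for ev in events:
        _insert_swd(samples, config, ev, rng, targets, power_scale, coherence_drop)

    rec = Recording(samples=samples, fs=config.fs, channels=config.layout)
    return rec, events


def generate_event_window(
    config: SessionConfig,
    duration_s: float | None = None,
    effect: EffectSpec | None = None,
    pad_s: float = 6.5,
) -> tuple[Recording, SWDEvent]:
    """Simulate a short excerpt containing exactly one seizure.

    The excerpt covers the event's 10%-margin analysis window plus ``pad_s``
    on each side (enough for 4 s spectral windows over the extended map grid
    with its clean pre-onset baseline), which makes per-seizure map
    computation cheap when whole sessions are not needed.
    """
    rng = np.random.default_rng(config.seed)
    if duration_s is None:
        duration_s = float(_draw_durations(1, config, rng)[0])
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    margin = 0.1 * duration_s
    onset = pad_s + margin
    total = duration_s + 2 * margin + 2 * pad_s
    n = int(round(total * config.fs))
    samples = _background(config, n, rng)
    event = SWDEvent(onset, onset + duration_s)
    if effect is not None:
        targets = frozenset(effect.resolve_targets(config.layout))
        ps, cd = effect.power_scale, effect.coherence_drop
    else:
        targets, ps, cd = frozenset(), 1.0, 0.0
    _insert_swd(samples, config, event, rng, targets, ps, cd)
    rec = Recording(samples=samples, fs=config.fs, channels=config.layout)
    return rec, event
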