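"""Spike-wave discharge (SWD) events and their detection.

An SWD is delimited by its first and last spike; the analysis window of each
event extends 10% of the event duration before onset and after offset, so the
pre-event margin that later serves as the normalization baseline scales with
seizure length.  Detection proposes candidate intervals with a 6-8 Hz
band-power hysteresis gate, then refines onset/offset to the first/last
detected spike.  Amplitude thresholds use a robust SD (1.4826 x median
absolute deviation) because the spikes themselves inflate the plain SD.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import signal as sps

from .signal_io import Recording


class UnanalyzableEventError(ValueError):
    """The 10%-margin analysis window would extend outside the recording."""


@dataclass(frozen=True)
class SWDEvent:
    """One seizure; onset/offset in seconds from recording start (half-open)."""

    onset_s: float
    offset_s: float
    source_channel: str = "consensus"

    def __post_init__(self) -> None:
        if not self.offset_s > self.onset_s:
            raise ValueError(
                f"event offset ({self.offset_s}) must exceed onset ({self.onset_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass(frozen=True)
class AnalysisWindow:
    """Event window with 10%-of-duration margins: [onset - 0.1 d, offset + 0.1 d]."""

    event: SWDEvent
    t0: float
    t1: float


def validate_event_list(events: Sequence[SWDEvent]) -> None:
    """Events must be sorted by onset and pairwise non-overlapping."""
    for a, b in zip(events, events[1:]):
        if b.onset_s < a.offset_s:
            raise ValueError(
                f"events overlap or are unsorted: ({a.onset_s}, {a.offset_s}) "
                f"and ({b.onset_s}, {b.offset_s})"
            )


def robust_sd(x: np.ndarray) -> float:
    """MAD-based robust standard deviation (consistent for Gaussian data)."""
    x = np.asarray(x, dtype=float)
    return 1.4826 * float(np.median(np.abs(x - np.median(x))))


def detect_spikes(
    trace: np.ndarray,
    fs: float,
    threshold_sd: float = 2.0,
    min_isi_ms: float = 100.0,
) -> np.ndarray:
    """Times (s) of |signal| local maxima above threshold_sd robust SDs.

    Peaks closer than min_isi_ms keep only the larger one.
    """
    trace = np.asarray(trace, dtype=float)
    if trace.size == 0:
        raise ValueError("empty trace")
    if threshold_sd <= 0:
        raise ValueError("threshold_sd must be positive")
    if min_isi_ms <= 0:
        raise ValueError("min_isi_ms must be positive")
    sd = robust_sd(trace)
    height = threshold_sd * sd if sd > 0 else np.inf
    distance = max(1, int(round(min_isi_ms * 1e-3 * fs)))
    idx, _ = sps.find_peaks(np.abs(trace - np.median(trace)), height=height, distance=distance)
    return idx / fs


def events_from_spikes(
    spike_times: np.ndarray,
    max_gap_s: float = 1.0,
    min_duration_s: float = 1.0,
    source_channel: str = "consensus",
) -> list[SWDEvent]:
    """Group spikes separated by <= max_gap_s; keep groups spanning >= min_duration_s.

    Each kept group becomes an event with onset at its first and offset at its
    last spike.
    """
    t = np.asarray(spike_times, dtype=float)
    if t.size == 0:
        return []
    if np.any(np.diff(t) < 0):
        raise ValueError("spike_times must be sorted")
    breaks = np.flatnonzero(np.diff(t) > max_gap_s)
    starts = np.concatenate([[0], breaks + 1])
    stops = np.concatenate([breaks, [t.size - 1]])
    events = []
    for a, b in zip(starts, stops):
        if t[b] - t[a] >= min_duration_s:
            events.append(SWDEvent(onset_s=t[a], offset_s=t[b], source_channel=source_channel))
    return events


def analysis_window(event: SWDEvent, recording_duration_s: float) -> AnalysisWindow:
    """Window (onset - 0.1 d, offset + 0.1 d); events whose window leaves the
    recording are rejected (never clipped) so baselines are always complete."""
    margin = 0.1 * event.duration_s
    t0 = event.onset_s - margin
    t1 = event.offset_s + margin
    if t0 < 0 or t1 > recording_duration_s:
        raise UnanalyzableEventError(
            f"analysis window ({t0:.3f}, {t1:.3f}) outside recording "
            f"[0, {recording_duration_s:.3f}]"
        )
    return AnalysisWindow(event=event, t0=t0, t1=t1)


def analyzable_events(
    events: Sequence[SWDEvent], recording_duration_s: float
) -> list[SWDEvent]:
    """Drop events flagged unanalyzable by the 10%-margin rule."""
    kept = []
    for e in events:
        try:
            analysis_window(e, recording_duration_s)
        except UnanalyzableEventError:
            continue
        kept.append(e)
    return kept


# ---------------------------------------------------------------------------
# Full detector: band-power gate + spike refinement + cross-channel consensus
# ---------------------------------------------------------------------------

def _bandpass(trace: np.ndarray, fs: float, band: tuple[float, float], order: int = 4) -> np.ndarray:
    nyq = fs / 2.0
    lo = max(band[0] / nyq, 1e-6)
    hi = min(band[1] / nyq, 0.999)
    sos = sps.butter(order, [lo, hi], btype="bandpass", output="sos")
    return sps.sosfiltfilt(sos, trace)


def _detect_channel(
    trace: np.ndarray,
    fs: float,
    band: tuple[float, float],
    on_mult: float,
    off_mult: float,
    spike_threshold_sd: float,
    min_isi_ms: float,
    max_gap_s: float,
    min_duration_s: float,
    label: str,
) -> list[SWDEvent]:
    bp = _bandpass(trace, fs, band)
    env = np.abs(sps.hilbert(bp))
    smooth_n = max(1, int(round(0.25 * fs)))
    kernel = np.ones(smooth_n) / smooth_n
    env = np.convolve(env, kernel, mode="same")
    # low quantile as the interictal floor: the median would sit at the ictal
    # level whenever seizures occupy more than half the session
    floor = float(np.quantile(env, 0.15))
    if floor <= 0:
        return []
    on = env > on_mult * floor
    off = env > off_mult * floor
    # hysteresis: grow each on-run outward while off stays true
    candidates = []
    runs = _bool_runs(on)
    for a, b in runs:
        while a > 0 and off[a - 1]:
            a -= 1
        while b < off.size and off[b]:
            b += 1
        candidates.append((a, b))
    candidates = _merge_intervals(candidates)

    # background level from outside the candidate gates: the whole-trace SD is
    # inflated when seizures occupy much of the session
    mask = np.ones(trace.size, dtype=bool)
    for a, b in candidates:
        mask[a:b] = False
    bg = trace[mask]
    bg_sd = robust_sd(bg) if bg.size > int(fs) else robust_sd(trace)
    if bg_sd <= 0:
        return []
    height = spike_threshold_sd * bg_sd
    events: list[SWDEvent] = []
    for a, b in candidates:
        seg = trace[a:b]
        idx, _ = sps.find_peaks(
            np.abs(seg - np.median(bg)),
            height=height,
            distance=max(1, int(round(min_isi_ms * 1e-3 * fs))),
        )
        spikes = (idx + a) / fs
        events.extend(
            events_from_spikes(spikes, max_gap_s=max_gap_s,
                               min_duration_s=min_duration_s, source_channel=label)
        )
    return _merge_events(events, max_gap_s, label)


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _merge_intervals(iv: list[tuple[int, int]]) -> list[tuple[int, int]]:
    if not iv:
        return []
    iv = sorted(iv)
    out = [iv[0]]
    for a, b in iv[1:]:
        if a <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], b))
        else:
            out.append((a, b))
    return out


def _merge_events(events: list[SWDEvent], max_gap_s: float, label: str) -> list[SWDEvent]:
    if not events:
        return []
    events = sorted(events, key=lambda e: e.onset_s)
    merged = [events[0]]
    for e in events[1:]:
        if e.onset_s - merged[-1].offset_s <= max_gap_s:
            merged[-1] = SWDEvent(merged[-1].onset_s, max(merged[-1].offset_s, e.offset_s),
                                  source_channel=label)
        else:
            merged.append(e)
    return merged


def detect_events(
    rec: Recording,
    band: tuple[float, float] = (6.0, 8.0),
    on_mult: float = 5.0,
    off_mult: float = 2.5,
    spike_threshold_sd: float = 4.5,
    min_isi_ms: float = 100.0,
    max_gap_s: float = 1.0,
    min_duration_s: float = 3.0,
    consensus_fraction: float = 0.5,
) -> list[SWDEvent]:
    """Detect SWDs on every channel and return cross-channel consensus events.

    Per channel, a hysteresis gate on the smoothed 6-8 Hz band envelope
    (on/off at multiples of the median envelope) proposes candidates, whose
    onset/offset are refined to the first/last suprathreshold spike.  Time
    points covered by at least ``consensus_fraction`` of channels form the
    consensus events (union of the agreeing per-channel events).
    """
    per_channel = [
        _detect_channel(rec.samples[i], rec.fs, band, on_mult, off_mult,
                        spike_threshold_sd, min_isi_ms, max_gap_s, min_duration_s,
                        rec.channels[i].label)
        for i in range(rec.n_channels)
    ]
    need = int(np.ceil(consensus_fraction * rec.n_channels))
    # vote on a 10 ms lattice
    dt = 0.01
    n_bins = int(np.ceil(rec.duration_s / dt)) + 1
    votes = np.zeros(n_bins, dtype=np.int32)
    for evs in per_channel:
        for e in evs:
            votes[int(e.onset_s / dt): int(np.ceil(e.offset_s / dt))] += 1
    # the first/last spike sits half a cycle inside the discharge: widen the
    # boundaries by half a fundamental period
    half_cycle = 0.5 / np.mean(band)
    consensus: list[SWDEvent] = []
    for a, b in _bool_runs(votes >= need):
        onset, offset = a * dt - half_cycle, b * dt + half_cycle
        if offset - onset >= min_duration_s:
            consensus.append(SWDEvent(max(onset, 0.0), min(offset, rec.duration_s),
                                      source_channel="consensus"))
    return consensus


def match_events(
    detected: Sequence[SWDEvent], truth: Sequence[SWDEvent]
) -> list[tuple[SWDEvent, SWDEvent]]:
    """Greedy one-to-one pairing of detected with ground-truth events by overlap."""
    pairs = []
    used = set()
    for t in truth:
        best, best_ov = None, 0.0
        for i, d in enumerate(detected):
            if i in used:
                continue
            ov = min(t.offset_s, d.offset_s) - max(t.onset_s, d.onset_s)
            if ov > best_ov:
                best, best_ov = i, ov
        if best is not None:
            used.add(best)
            pairs.append((detected[best], t))
    return pairs
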