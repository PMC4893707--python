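"""Recording container and file I/O.

Recordings are multi-channel local field potentials in microvolts with an
electrode layout (hemisphere, anteroposterior and mediolateral stereotaxic
coordinates in mm).  Two on-disk formats are supported:

* a lossless HDF5 container (``/signals`` as float32, ``/fs``, and a
  ``/channels`` table) — the primary format;
* EDF (European Data Format), 16-bit quantized, for interoperability with
  standard electrophysiology viewers.  Channel coordinates are stored in the
  per-signal transducer field as ``hemisphere=...;ap=...;ml=...``.

Event lists are plain CSV with ``onset_s,offset_s`` columns; times are seconds
from recording start, intervals half-open ``[onset, offset)``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import h5py
import numpy as np
import pandas as pd


class FormatError(ValueError):
    """A file violates the expected on-disk layout; the message names the field."""


@dataclass(frozen=True)
class Channel:
    """One electrode: label, hemisphere and stereotaxic position (mm)."""

    label: str
    hemisphere: str = "left"
    ap_mm: float = float("nan")
    ml_mm: float = float("nan")

    def __post_init__(self) -> None:
        if self.hemisphere not in ("left", "right"):
            raise ValueError(f"hemisphere must be 'left' or 'right', got {self.hemisphere!r}")


@dataclass
class Recording:
    """Multi-channel signal matrix (channels x samples, microvolts) at rate fs."""

    samples: np.ndarray
    fs: float
    channels: tuple[Channel, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2D channels x time array")
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")
        if not self.channels:
            self.channels = tuple(Channel(label=f"ch{i}") for i in range(self.samples.shape[0]))
        self.channels = tuple(self.channels)
        if len(self.channels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel descriptors for {self.samples.shape[0]} signal rows"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            dupes = sorted({l for l in labels if labels.count(l) > 1})
            raise ValueError(f"duplicate channel labels: {dupes}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def channel_index(self, label: str) -> int:
        for i, c in enumerate(self.channels):
            if c.label == label:
                return i
        raise KeyError(f"no channel labelled {label!r}")

    def trace(self, label: str) -> np.ndarray:
        return self.samples[self.channel_index(label)]

    def hemisphere_labels(self, hemisphere: str) -> list[str]:
        return [c.label for c in self.channels if c.hemisphere == hemisphere]


# ---------------------------------------------------------------------------
# HDF5 container
# ---------------------------------------------------------------------------

def write_recording_hdf5(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signals", data=rec.samples.astype(np.float32))
        f.create_dataset("fs", data=float(rec.fs))
        g = f.create_group("channels")
        g.create_dataset("label", data=[c.label for c in rec.channels])
        g.create_dataset("hemisphere", data=[c.hemisphere for c in rec.channels])
        g.create_dataset("ap_mm", data=[c.ap_mm for c in rec.channels])
        g.create_dataset("ml_mm", data=[c.ml_mm for c in rec.channels])


def _read_recording_hdf5(path: str | Path) -> Recording:
    with h5py.File(path, "r") as f:
        for key in ("signals", "fs", "channels"):
            if key not in f:
                raise FormatError(f"HDF5 container missing '/{key}'")
        sig = np.asarray(f["signals"], dtype=np.float64)
        fs = float(f["fs"][()])
        g = f["channels"]
        labels = [s.decode() if isinstance(s, bytes) else str(s) for s in g["label"][()]]
        hemis = [s.decode() if isinstance(s, bytes) else str(s) for s in g["hemisphere"][()]]
        ap = np.asarray(g["ap_mm"], dtype=float)
        ml = np.asarray(g["ml_mm"], dtype=float)
    channels = tuple(
        Channel(label=l, hemisphere=h, ap_mm=a, ml_mm=m)
        for l, h, a, m in zip(labels, hemis, ap, ml)
    )
    try:
        return Recording(samples=sig, fs=fs, channels=channels)
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------
# EDF: 256-byte ASCII main header + 256 bytes per signal, then data records of
# little-endian int16.  We use 1-second records, so fs must be a whole number.

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


def _ascii(value: object, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_recording_edf(rec: Recording, path: str | Path) -> None:
    fs = rec.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1 s record
    n_records = int(np.ceil(rec.n_samples / spr))
    ns = rec.n_channels

    # physical range per channel, symmetric, padded so flat signals stay valid
    phys_max = np.maximum(np.abs(rec.samples).max(axis=1), 1.0) * 1.0000001

    header = b"".join([
        _ascii("0", 8),
        _ascii("X X X X", 80),                       # patient id
        _ascii("Startdate X X X X", 80),             # recording id
        _ascii("01.01.00", 8), _ascii("00.00.00", 8),
        _ascii(256 * (1 + ns), 8),
        _ascii("", 44),
        _ascii(n_records, 8),
        _ascii("1", 8),                              # record duration (s)
        _ascii(ns, 4),
    ])
    transducers = [
        f"hemisphere={c.hemisphere};ap={c.ap_mm:g};ml={c.ml_mm:g}" for c in rec.channels
    ]
    fields: list[bytes] = []
    for getter, width in [
        (lambda i: rec.channels[i].label, 16),
        (lambda i: transducers[i], 80),
        (lambda i: "uV", 8),
        (lambda i: f"{-phys_max[i]:.7g}"[:8], 8),
        (lambda i: f"{phys_max[i]:.7g}"[:8], 8),
        (lambda i: _EDF_DIG_MIN, 8),
        (lambda i: _EDF_DIG_MAX, 8),
        (lambda i: "", 80),
        (lambda i: spr, 8),
        (lambda i: "", 32),
    ]:
        fields.extend(_ascii(getter(i), width) for i in range(ns))
    header += b"".join(fields)

    gain = phys_max / _EDF_DIG_MAX
    padded = np.zeros((ns, n_records * spr), dtype=np.float64)
    padded[:, : rec.n_samples] = rec.samples
    digital = np.clip(np.round(padded / gain[:, None]), _EDF_DIG_MIN, _EDF_DIG_MAX).astype("<i2")
    with open(path, "wb") as f:
        f.write(header)
        # record-major: for each record all channels consecutively
        blocks = digital.reshape(ns, n_records, spr).transpose(1, 0, 2)
        f.write(np.ascontiguousarray(blocks).tobytes())


def _parse_transducer(text: str) -> dict:
    out: dict = {}
    for part in text.split(";"):
        if "=" in part:
            k, v = part.split("=", 1)
            out[k.strip()] = v.strip()
    return out


def _read_recording_edf(path: str | Path) -> Recording:
    with open(path, "rb") as f:
        head = f.read(256)
        if len(head) < 256:
            raise FormatError("EDF header truncated (file shorter than 256 bytes)")

        def s(a: int, b: int) -> str:
            return head[a:b].decode("ascii", errors="replace").strip()

        try:
            n_records = int(s(236, 244))
            record_dur = float(s(244, 252))
            ns = int(s(252, 256))
        except ValueError as exc:
            raise FormatError(f"EDF header numeric field unreadable: {exc}") from exc
        if ns <= 0:
            raise FormatError(f"EDF header: number of signals must be positive, got {ns}")
        sig_head = f.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise FormatError("EDF signal headers truncated")

        def col(idx: int, width: int) -> list[str]:
            # signal headers are field-major
            offsets = [0, 16 * ns, 96 * ns, 104 * ns, 112 * ns, 120 * ns, 128 * ns, 136 * ns,
                       216 * ns, 224 * ns]
            base = offsets[idx]
            return [
                sig_head[base + i * width: base + (i + 1) * width].decode("ascii", "replace").strip()
                for i in range(ns)
            ]

        labels = col(0, 16)
        transducers = col(1, 80)
        try:
            phys_min = np.array([float(x) for x in col(3, 8)])
            phys_max = np.array([float(x) for x in col(4, 8)])
            dig_min = np.array([float(x) for x in col(5, 8)])
            dig_max = np.array([float(x) for x in col(6, 8)])
            spr = np.array([int(x) for x in col(8, 8)])
        except ValueError as exc:
            raise FormatError(f"EDF signal header numeric field unreadable: {exc}") from exc
        if len(set(spr.tolist())) != 1:
            raise FormatError("EDF: signals with differing sampling rates are not supported")
        spr0 = int(spr[0])
        if record_dur <= 0:
            raise FormatError(f"EDF header: record duration must be positive, got {record_dur}")
        fs = spr0 / record_dur
        raw = np.frombuffer(f.read(2 * ns * spr0 * n_records), dtype="<i2")

    if raw.size != ns * spr0 * n_records:
        raise FormatError("EDF data section shorter than header declares")
    digital = raw.reshape(n_records, ns, spr0).transpose(1, 0, 2).reshape(ns, -1)
    gain = (phys_max - phys_min) / (dig_max - dig_min)
    offset = phys_min - gain * dig_min
    samples = digital * gain[:, None] + offset[:, None]

    channels = []
    for lab, trans in zip(labels, transducers):
        meta = _parse_transducer(trans)
        channels.append(Channel(
            label=lab,
            hemisphere=meta.get("hemisphere", "left"),
            ap_mm=float(meta["ap"]) if "ap" in meta else float("nan"),
            ml_mm=float(meta["ml"]) if "ml" in meta else float("nan"),
        ))
    try:
        return Recording(samples=samples, fs=fs, channels=tuple(channels))
    except ValueError as exc:
        raise FormatError(str(exc)) from exc


def write_recording(rec: Recording, path: str | Path, format: str | None = None) -> None:
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        write_recording_hdf5(rec, path)
    else:
        write_recording_edf(rec, path)


def read_recording(path: str | Path, format: str | None = None) -> Recording:
    """Read a Recording from EDF or the HDF5 container.

    Channel order is preserved exactly as stored; values are microvolts.
    """
    fmt = _infer_format(path, format)
    if fmt == "hdf5":
        return _read_recording_hdf5(path)
    return _read_recording_edf(path)


def _infer_format(path: str | Path, format: str | None) -> str:
    if format is not None:
        fmt = format.lower()
        if fmt in ("hdf5", "h5"):
            return "hdf5"
        if fmt == "edf":
            return "edf"
        raise ValueError(f"unknown format {format!r}; expected 'edf' or 'hdf5'")
    suffix = Path(path).suffix.lower()
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    if suffix == ".edf":
        return "edf"
    raise ValueError(f"cannot infer format from suffix {suffix!r}; pass format=")


# ---------------------------------------------------------------------------
# Event CSV
# ---------------------------------------------------------------------------

def write_events(events: Sequence, path: str | Path) -> None:
    """Write SWD events as CSV with columns onset_s,offset_s (full precision)."""
    df = pd.DataFrame(
        {"onset_s": [e.onset_s for e in events], "offset_s": [e.offset_s for e in events]}
    )
    df.to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# Results container (TF maps and stat results, with axes and provenance)
# ---------------------------------------------------------------------------

def write_tfmap(map_obj, group: "h5py.Group") -> None:
    """Store a TFMap in an HDF5 group: values + both axes + metadata attrs."""
    group.create_dataset("values", data=map_obj.values.astype(np.float64))
    group.create_dataset("times", data=map_obj.grid.times)
    group.create_dataset("freqs", data=map_obj.grid.freqs)
    group.attrs["kind"] = map_obj.kind
    group.attrs["window_s"] = map_obj.grid.window_s
    group.attrs["rescaled"] = bool(map_obj.rescaled)
    if map_obj.channel is not None:
        group.attrs["channel"] = map_obj.channel
    if map_obj.pair is not None:
        group.attrs["pair"] = "-".join(map_obj.pair)
    if map_obj.event_id is not None:
        group.attrs["event_id"] = map_obj.event_id
    for k, v in map_obj.meta.items():
        if isinstance(v, (int, float, str, bool)):
            group.attrs[f"meta_{k}"] = v


def read_tfmap(group: "h5py.Group"):
    from .spectral import TFGrid, TFMap

    grid = TFGrid(times=np.asarray(group["times"]), freqs=np.asarray(group["freqs"]),
                  window_s=float(group.attrs["window_s"]))
    pair = group.attrs.get("pair")
    meta = {k[5:]: group.attrs[k] for k in group.attrs if k.startswith("meta_")}
    return TFMap(
        grid=grid,
        values=np.asarray(group["values"]),
        kind=str(group.attrs["kind"]),
        channel=str(group.attrs["channel"]) if "channel" in group.attrs else None,
        pair=tuple(str(pair).split("-", 1)) if pair is not None else None,
        event_id=str(group.attrs["event_id"]) if "event_id" in group.attrs else None,
        rescaled=bool(group.attrs["rescaled"]),
        meta=meta,
    )


def write_stat_result(result, group: "h5py.Group") -> None:
    group.create_dataset("t_values", data=result.t_values)
    if result.sig_mask is not None:
        group.create_dataset("sig_mask", data=result.sig_mask.astype(np.uint8))
    group.create_dataset("times", data=result.grid.times)
    group.create_dataset("freqs", data=result.grid.freqs)
    group.attrs["df"] = result.df
    group.attrs["n_pre"] = result.n_pre
    group.attrs["n_post"] = result.n_post
    group.attrs["direction"] = result.direction
    if result.alpha is not None:
        group.attrs["alpha"] = result.alpha
        group.attrs["u_star"] = result.u_star
        group.attrs["resels"] = result.resels


def read_events(path: str | Path) -> list:
    from .swd_events import SWDEvent  # local import to avoid a cycle

    df = pd.read_csv(path, float_precision="round_trip")
    for colname in ("onset_s", "offset_s"):
        if colname not in df.columns:
            raise FormatError(f"event CSV missing column '{colname}'")
    events = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        if not row.offset_s > row.onset_s:
            raise FormatError(
                f"event CSV row {i}: offset_s ({row.offset_s}) must exceed onset_s ({row.onset_s})"
            )
        events.append(SWDEvent(onset_s=float(row.onset_s), offset_s=float(row.offset_s)))
    return events
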