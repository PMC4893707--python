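"""End-to-end orchestration: simulate -> detect -> tfr -> stats -> bands -> geometry.

Each stage writes its artifacts under the output directory so stages can be
re-run independently; a provenance file records the config hash, seed and
package version.  All randomness derives from the single pipeline seed, so a
given (config, seed) pair reproduces every output byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .band_stats import (DEFAULT_BANDS, MapRecord, band_summary, central_electrodes,
                         interictal_band_stats, posthoc_vs_baseline, rm_anova_2way)
from .beam_geometry import TransectionPlan, compute_footprint
from .rft_inference import run_inference
from .signal_io import (write_events, write_recording_hdf5, write_stat_result, write_tfmap)
from .spectral import default_grid, interictal_band_fft, sliding_welch_coherence, sliding_welch_power
from .swd_events import analysis_window, analyzable_events, detect_events
from .synth_lfp import EffectSpec, SessionConfig, default_layout, generate_session
from .tf_maps import normalize_map, rescale_time, smooth_map

import h5py

logger = logging.getLogger("swdmaps")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and context."""


@dataclass
class PipelineConfig:
    """Study-level configuration for the synthetic end-to-end pipeline."""

    n_animals: int = 4
    timepoints: tuple[str, ...] = ("baseline", "1w")
    session: dict = field(default_factory=dict)          # SessionConfig overrides
    effect: dict | None = None                           # EffectSpec kwargs, applied post-baseline
    alpha: float = 0.05
    band: tuple[float, float] = (6.0, 8.0)
    bands: dict = field(default_factory=lambda: dict(DEFAULT_BANDS))
    n_rescaled_bins: int = 121
    fwhm_time_fraction: float = 0.05
    fwhm_freq_hz: float = 5.0
    use_detector: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.n_animals < 2:
            raise ValueError("need >= 2 animals")
        if len(self.timepoints) < 2 or self.timepoints[0] != "baseline":
            raise ValueError("timepoints must start with 'baseline' and include a post timepoint")


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as f:
        raw = yaml.safe_load(f) or {}
    if "timepoints" in raw:
        raw["timepoints"] = tuple(raw["timepoints"])
    if "band" in raw:
        raw["band"] = tuple(raw["band"])
    if "bands" in raw:
        raw["bands"] = {k: tuple(v) for k, v in raw["bands"].items()}
    return PipelineConfig(**raw)


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha1(blob).hexdigest()[:12]


def _session_seed(base: int, animal: int, tp: int) -> int:
    return (base * 1_000_003 + animal * 1009 + tp * 101 + 7) % (2**31 - 1)


def _session_config(cfg: PipelineConfig, seed: int) -> SessionConfig:
    kw = dict(cfg.session)
    kw["seed"] = seed
    return SessionConfig(**kw)


def event_maps(rec, event, grid_band=(4.0, 20.0), n_bins=121,
               fwhm_time_fraction=0.05, fwhm_freq_hz=5.0,
               channels=None, pairs=None, event_id=None):
    """Normalized, rescaled, smoothed power (and coherence) maps for one event.

    The map grid covers the event's 10%-margin analysis window, extended half
    a spectral window to the left so that a clean baseline exists: the
    z-scoring baseline is the set of window centers whose whole 4 s window
    draws pre-onset signal (their center span equals the 10% pre-SWD margin).
    Centers closer to onset would mix ictal power into the baseline mean/SD
    and de-sensitize the normalization.
    """
    win = analysis_window(event, rec.duration_s)
    half = 2.0  # half spectral window
    # round the grid end up so interpolation onto the rescaled axis never
    # extrapolates past the last window center
    dt = 0.1
    t_start = win.t0 - half
    t_stop = t_start + dt * np.ceil((win.t1 - t_start) / dt - 1e-9)
    grid = default_grid(t_start, t_stop, dt=dt, f_lo=grid_band[0], f_hi=grid_band[1])
    if grid.times[0] - half < 0 or grid.times[-1] + half > rec.duration_s:
        raise ValueError("recording too short for the event's spectral windows")
    baseline = (t_start, event.onset_s - half)
    out = []
    for label in (channels or []):
        m = sliding_welch_power(rec.trace(label), rec.fs, grid,
                                channel=label, event_id=event_id)
        m = normalize_map(m, baseline)
        m = rescale_time(m, event.onset_s, event.offset_s, n_bins)
        m = smooth_map(m, fwhm_time_fraction, fwhm_freq_hz)
        out.append(m)
    for a, b in (pairs or []):
        m = sliding_welch_coherence(rec.trace(a), rec.trace(b), rec.fs, grid,
                                    pair=(a, b), event_id=event_id)
        m = normalize_map(m, baseline)
        m = rescale_time(m, event.onset_s, event.offset_s, n_bins)
        m = smooth_map(m, fwhm_time_fraction, fwhm_freq_hz)
        out.append(m)
    return out


def _adjacent_pairs(labels: list[str]) -> list[tuple[str, str]]:
    return list(zip(labels, labels[1:]))


def _interictal_epoch(rec, events, idx, max_len_s=5.0, guard_s=1.0):
    """Background segment of 2-10 s ending guard_s before event idx, or None."""
    ev = events[idx]
    prev_end = events[idx - 1].offset_s + guard_s if idx > 0 else 0.0
    t1 = ev.onset_s - guard_s
    t0 = max(prev_end, t1 - max_len_s)
    if t1 - t0 < 2.0:
        return None
    i0, i1 = int(t0 * rec.fs), int(t1 * rec.fs)
    return rec.samples[:, i0:i1]


def run_pipeline(cfg: PipelineConfig, outdir: str | Path) -> dict:
    """Run every stage; returns a summary dict of key outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    provenance = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                  "swdmaps_version": __version__}
    (outdir / "provenance.json").write_text(json.dumps(provenance, indent=2) + "\n")

    layout = _session_config(cfg, 0).layout
    left3 = central_electrodes(layout, "left")
    right3 = central_electrodes(layout, "right")
    channels = left3 + right3
    pairs = _adjacent_pairs(left3) + _adjacent_pairs(right3)

    records: list[MapRecord] = []
    interictal_rows = []
    maps_by_channel: dict[str, dict[str, dict[str, list]]] = {
        c: {f"a{a}": {"pre": [], "post": []} for a in range(cfg.n_animals)} for c in channels
    }

    try:
        for a in range(cfg.n_animals):
            for ti, tp in enumerate(cfg.timepoints):
                scfg = _session_config(cfg, _session_seed(cfg.seed, a, ti))
                effect = None
                if cfg.effect is not None:
                    eff = EffectSpec(**cfg.effect)
                    if ti >= max(eff.onset_session, 1):
                        effect = eff
                logger.info("simulate: animal %d timepoint %s", a, tp)
                rec, truth = generate_session(scfg, effect)
                tag = f"a{a}_{tp}"
                write_recording_hdf5(rec, outdir / f"session_{tag}.h5")
                write_events(truth, outdir / f"events_{tag}.csv")

                events = detect_events(rec) if cfg.use_detector else truth
                events = analyzable_events(events, rec.duration_s)
                for k, ev in enumerate(events):
                    maps = event_maps(
                        rec, ev, n_bins=cfg.n_rescaled_bins,
                        fwhm_time_fraction=cfg.fwhm_time_fraction,
                        fwhm_freq_hz=cfg.fwhm_freq_hz,
                        channels=channels, pairs=pairs, event_id=f"{tag}_ev{k}",
                    )
                    for m in maps:
                        if m.kind == "z-power":
                            side = next(c.hemisphere for c in layout if c.label == m.channel)
                            records.append(MapRecord(f"a{a}", tp, side, "power", m.channel, m))
                            cond = "pre" if tp == "baseline" else (
                                "post" if tp == cfg.timepoints[1] else None)
                            if cond:
                                maps_by_channel[m.channel][f"a{a}"][cond].append(m)
                        else:
                            side = next(c.hemisphere for c in layout if c.label == m.pair[0])
                            records.append(MapRecord(f"a{a}", tp, side, "coherence",
                                                     f"pair:{m.pair[0]}-{m.pair[1]}", m))
                # interictal epochs (background before each seizure)
                if tp in ("baseline", cfg.timepoints[1]):
                    cond = "pre" if tp == "baseline" else "post"
                    amps = []
                    for k in range(len(events)):
                        seg = _interictal_epoch(rec, events, k)
                        if seg is None:
                            continue
                        for lab in channels:
                            amps.append(interictal_band_fft(
                                seg[rec.channel_index(lab)], rec.fs, cfg.bands))
                    if amps:
                        mean_amp = pd.concat(amps, axis=1).mean(axis=1)
                        for band_name, amp in mean_amp.items():
                            interictal_rows.append((f"a{a}", cond, band_name, amp))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage 'simulate/tfr' failed: {exc}") from exc

    # ---- stats stage: per-channel pooled inference -------------------------
    stats_rows = []
    try:
        with h5py.File(outdir / "results.h5", "w") as f:
            f.attrs.update(provenance)
            for c in channels:
                pre = [m for a in maps_by_channel[c].values() for m in a["pre"]]
                post = [m for a in maps_by_channel[c].values() for m in a["post"]]
                res = run_inference(pre, post, alpha=cfg.alpha)
                g = f.create_group(f"stats/{c}")
                write_stat_result(res, g)
                np.savetxt(outdir / f"sigmask_{c}.csv",
                           res.sig_mask.astype(int), fmt="%d", delimiter=",")
                stats_rows.append((c, res.u_star, int(res.sig_mask.sum())))
            for i, rec_m in enumerate(records[: min(len(records), 8)]):
                write_tfmap(rec_m.map, f.create_group(f"maps/{rec_m.animal}_{i}"))
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'stats' failed: {exc}") from exc
    pd.DataFrame(stats_rows, columns=["channel", "u_star", "n_sig_pixels"]).to_csv(
        outdir / "stats_summary.csv", index=False, float_format="%.6g")

    # ---- bands stage -------------------------------------------------------
    try:
        summary = band_summary(records, layout, band=cfg.band)
        summary.to_csv(outdir / "band_summary.csv", index=False, float_format="%.10g")
        for measure in summary.measure.unique():
            sub = summary[summary.measure == measure]
            table = rm_anova_2way(sub)
            table.to_csv(outdir / f"anova_{measure}.csv", index=False, float_format="%.10g")
            ph = posthoc_vs_baseline(sub)
            ph.to_csv(outdir / f"posthoc_{measure}.csv", index=False, float_format="%.10g")
        inter = pd.DataFrame(interictal_rows,
                             columns=["animal", "condition", "band", "amplitude"])
        inter.to_csv(outdir / "interictal_amplitudes.csv", index=False, float_format="%.10g")
        itable, iph = interictal_band_stats(inter)
        itable.to_csv(outdir / "interictal_anova.csv", index=False, float_format="%.10g")
        iph.to_csv(outdir / "interictal_posthoc.csv", index=False, float_format="%.10g")
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(f"stage 'bands' failed: {exc}") from exc

    # ---- geometry stage ----------------------------------------------------
    fp = compute_footprint(TransectionPlan())
    geometry = {
        "thickness_um": fp.thickness_um,
        "min_caliper_width_mm": fp.min_caliper_width_mm,
        "max_diameter_mm": fp.max_diameter_mm,
        "area_mm2": fp.area_mm2,
        "n_vertices": fp.n_vertices,
        "vertices_mm": fp.footprint_polygon.tolist(),
    }
    (outdir / "geometry.json").write_text(json.dumps(geometry, indent=2) + "\n")

    return {"n_map_records": len(records), "stats": stats_rows, "geometry": geometry,
            "outdir": str(outdir)}
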