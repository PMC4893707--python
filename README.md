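# swdmaps

Time-frequency mapping and statistics of spike-wave discharges (SWDs) in
multi-channel cortical LFP recordings, plus the interlaced-microbeam
geometry of radiosurgical cortical micro-transections.

## What problem this solves

In rodent models of absence epilepsy (e.g. the GAERS rat), seizures appear
as frequent, stereotyped ~7 Hz spike-wave discharges recorded simultaneously
on many cortical electrodes. An intervention that cuts horizontal
intracortical fibers — here, thin tissue transections made by interlaced
synchrotron X-ray microbeams — is expected to reduce the *power* and the
*inter-electrode coherence* of the discharges on the treated side while
leaving the background (interictal) signal untouched. Quantifying that
requires comparing seizures of different durations, recorded at different
times, across animals, over a whole time-frequency plane — with honest
control of multiple comparisons.

`swdmaps` implements that analysis chain for electrophysiologists:

1. **Event handling** — SWDs delimited by first/last spike; each event gets
   an analysis window with 10%-of-duration margins.
2. **Spectral estimation** — sliding Welch power and magnitude-squared
   coherence on a 4–20 Hz × 0.1 Hz grid, 4 s windows every 100 ms.
3. **Normalization & registration** — per-frequency z-scoring against the
   pre-seizure baseline; linear rescaling of seizure time onto a common axis
   (onset = 0, offset = 1); Gaussian smoothing (FWHM 5% of duration × 5 Hz).
4. **Inference** — fixed-effects pooling over animals and seizures,
   pixel-wise two-sample t-maps, and a family-wise-error-corrected threshold
   u\* from random field theory: u\* solves
   E[EC(u)] = Σ_d R_d ρ_d(u, ν) = α, with resels R_d from the known kernel
   smoothness and ρ_d the t-field Euler-characteristic densities.
5. **Band statistics** — 6–8 Hz band, central-3 electrodes per hemisphere,
   percent-of-baseline time-courses, two-way repeated-measures ANOVA
   (time × cortical side) with Bonferroni/Šidák post-hocs; interictal FFT
   band amplitudes with a time × band ANOVA.
6. **Beam geometry** — stacked thickness w + (n−1)s of the interlaced
   microbeams and the in-plane intersection polygon of the port strips, with
   rotating-calipers width.
7. **Synthetic sessions** — a calibrated generator of GAERS-like recordings
   (1/f background, coupled channels, harmonic-rich 7 Hz bursts at 62.2/h,
   24.8 ± 2.7 s) with injectable treatment effects, used as ground truth for
   validating the whole chain.

## Worked example

Geometry of the default irradiation plan — four 50 µm-wide, 2 mm-high
microbeams through ports at 0°, 45°, 90°, −45° with a 50 µm step:

```python
>>> from swdmaps import TransectionPlan, compute_footprint
>>> fp = compute_footprint(TransectionPlan())
>>> fp.thickness_um, fp.min_caliper_width_mm, round(fp.max_diameter_mm, 4)
(200.0, 2.0, 2.1648)
```

The beams stack into a 200 µm-thick slab, and their in-plane footprint is a
regular octagon 2.0 mm across the flats (2.165 mm across the vertices) —
the "200 µm × 2 mm" transection target.

A small end-to-end run on synthetic data (two animals, baseline vs one week
post-treatment, seizure power on the left halved):

```python
from swdmaps.pipeline import PipelineConfig, run_pipeline
cfg = PipelineConfig(n_animals=2, timepoints=("baseline", "1w"),
                     session={"fs": 250.0, "duration_s": 180.0,
                              "swd_rate_per_h": 50.0},
                     effect={"power_scale": 0.5}, seed=3)
run_pipeline(cfg, "demo_out")
```

`demo_out/stats_summary.csv` then reads:

```
channel   u_star  n_sig_pixels
L2       6.58992          1300
L3       6.58992             0
L4       6.58992          1143
R2       6.58992             0
R3       6.58992             0
R4       6.58992             0
```

Left-hemisphere channels show time-frequency pixels whose t values exceed
the corrected threshold u\* ≈ 6.59 (the threshold is high because only ~4
seizures per condition enter this toy run); no right-hemisphere pixel is
significant anywhere. `demo_out/posthoc_power.csv` shows the matching
band-level picture — left 6–8 Hz power at ~52% of baseline
(mean_diff ≈ −48.3), right at ~101%:

```
side   timepoint  mean_diff        t      p_unc     p_adj
left   1w        -48.329581 -8.883758  0.071361  0.142721
right  1w          0.834517  0.105405  0.933144  1.000000
```

(with only two animals the paired t-test has a single degree of freedom, so
the per-animal drop is large but not significant — the full-size validation
runs in the test suite use four animals and reach significance).

The same stages are available from the shell:

```bash
swdmaps simulate --config cfg.yaml --out out/     # synthetic session + events CSV
swdmaps detect out/session.h5 --out events.csv    # SWD detection
swdmaps geometry                                  # transection geometry as JSON
swdmaps all --config cfg.yaml --seed 3 --out out/ # the whole pipeline
```

## Layout

```
src/swdmaps/
  synth_lfp.py      synthetic GAERS-like sessions with ground truth
  signal_io.py      Recording container; EDF/HDF5/CSV readers & writers
  swd_events.py     spikes, events, analysis windows, detection
  spectral.py       sliding Welch power/coherence, interictal band FFT
  tf_maps.py        baseline z-normalization, time rescaling, smoothing
  rft_inference.py  pooling, t-maps, resels, RFT threshold
  band_stats.py     band summaries, RM-ANOVA, post-hocs
  beam_geometry.py  interlaced transection geometry
  pipeline.py, cli.py   orchestration and the `swdmaps` command
docs/methods.md     model, assumptions, parameter choices, limitations
```
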