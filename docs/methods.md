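# Methods

`swdmaps` analyses spike-wave discharges (SWDs) — the stereotyped ~7 Hz,
high-amplitude seizure oscillations of absence epilepsy — in multi-channel
local field potential (LFP) recordings from a bilateral two-row cortical
electrode montage. Its statistical core is event-locked time-frequency
mapping with baseline z-normalization, seizure time rescaling, Gaussian
smoothing and random-field-theory (RFT) corrected inference, followed by
band-level repeated-measures statistics. A geometry module computes the
interlaced-microbeam transection target used to perturb the cortex, and a
synthetic session generator provides ground-truth data for validation.

## Time-frequency estimation

Power and magnitude-squared coherence are estimated with a sliding Welch
scheme on a fixed grid: frequencies 4–20 Hz in 0.1 Hz steps (161 bins),
window centers every 100 ms, window length 4 s. Within each window, seven
1 s Hann-tapered, constant-detrended sub-segments at 50% overlap are
averaged; their DFTs are evaluated directly at the grid frequencies, which
is equivalent to zero-padding and interpolates the spectrum without adding
resolution (the native resolution of a 1 s sub-segment is ~1 Hz). The
sub-segment count K = 7 is recorded in map metadata because the small-sample
coherence bias is ≈ 1/K. Power is one-sided PSD in µV²/Hz.

## Event windows, normalization, rescaling, smoothing

An SWD is delimited by its first and last spike. The analysis window of each
event adds margins of 10% of the event duration before onset and after
offset. Maps are z-scored per frequency against the pre-onset baseline:
subtract the baseline mean, divide by the baseline sample SD (sample SD,
ddof = 1; the population/sample choice is not otherwise determined).

One subtlety matters for sensitivity: with 4 s windows indexed by their
centers, any center within 2 s of onset draws ictal signal, so using all
pre-onset centers as "baseline" leaks seizure power into the baseline mean
and SD. The pipeline therefore computes each event's map on a grid extended
half a window to the left and takes as baseline exactly those centers whose
whole 4 s window precedes onset; the span of these centers equals the 10%
pre-SWD margin. Without this, the z maps become nearly invariant to genuine
ictal power changes.

The time axis of each normalized map is then linearly rescaled so onset maps
to 0 and offset to 1, with the map spanning [−0.1, 1.1] in 121 bins
(n_bins = 121 keeps at least the native 0.1 s resolution for the shortest
admitted seizures). All events thus share one axis and can be stacked.
Finally maps are smoothed with a separable Gaussian kernel, FWHM = 5% of the
seizure duration in time (5 bins on the unit axis) and 5 Hz in frequency
(50 bins). The kernel is truncated at ±4 SD and renormalized at the map
edges (division by the smoothed indicator), which preserves local mass
without contaminating borders with implicit zeros.

## Inference

Seizure maps from all animals are pooled per condition (fixed-effects
analysis) and compared pixel-wise with a pooled-variance two-sample t-test,
df = n₁ + n₂ − 2, testing pre > post by default (the directional claim of a
power reduction); a paired variant exists for matched counts, and the
two-sided option splits alpha. Note the source analysis description
("paired two-sample t-test" on unpaired, unequal-size seizure sets) is
internally contradictory; the unpaired pooled test is the default here.

Family-wise error over the time-frequency plane is controlled with RFT: the
corrected threshold u* solves

    E[EC(u)] = R₀ρ₀(u) + R₁ρ₁(u) + R₂ρ₂(u) = α,

where ρ_d are the standard Euler-characteristic densities of a t-field and
the resel counts of the T×F rectangular field are R₀ = 1,
R₁ = (T−1)/f_t + (F−1)/f_f, R₂ = (T−1)(F−1)/(f_t f_f) with FWHMs f_t, f_f in
bin units. Smoothness is taken from the applied kernel, which is known by
construction, rather than estimated from residuals. The equation is solved
by bracketed root-finding (bisection/Brent to 1e-8) starting from the
uncorrected t quantile. Because the maps carry intrinsic correlation from
overlapping Welch windows on top of the applied kernel, the kernel-only
resel count overstates the true roughness, making the threshold mildly
conservative; Monte-Carlo calibration in the test suite confirms the
empirical family-wise error stays at or below alpha.

## Band-level statistics

For the time-course analysis, maps are reduced to the 6–8 Hz band (which
carries most SWD power and coherence), the ictal portion of the rescaled
axis, and the three central anteroposterior electrode positions of each
hemisphere row — the positions flanked by the transection planes. One value
per animal × timepoint × hemisphere × measure is expressed as percent of
that animal's own baseline. These feed a two-way repeated-measures ANOVA
with time as between factor and cortical side as within factor, implemented
by balanced mixed-design sum-of-squares partitioning (cross-checked against
`pingouin.mixed_anova` in the tests). Declaring time "between" while the
same animals span all timepoints is internally inconsistent; the as-stated
mode treats each animal × timepoint cell as an independent subject unit, and
a fully-within mode is provided. Post-hoc comparisons test each post
timepoint against baseline per side (paired t across animals), corrected
over the whole comparison family — Bonferroni by default, Šidák optionally,
with stars at 0.05/0.01.

Interictal background is quantified on 2–10 s epochs ending shortly before
seizure onsets: single-sided FFT amplitude averaged per band. Band edges
follow rodent-LFP convention — delta 1–4, theta 4–8, alpha 8–12, beta 12–30,
low gamma 30–55, high gamma 65–120, epsilon 120–600 Hz; 55–65 Hz is skipped
(mains notch region). Bands are configurable, and analyses at reduced
sampling rates drop bands above the Nyquist frequency. Pre/post amplitudes
enter a time × band repeated-measures ANOVA with per-band post-hocs.

## Beam geometry

A transection is delivered as one 50 µm-wide, 2 mm-high microbeam through
four ports at 45° angular spacing with a 50 µm lateral step between ports.
Along the step axis the beams stack to thickness w + (n−1)s = 200 µm; a
warning is raised if step > width (non-contiguous slabs). In the plane, each
port sweeps a strip as wide as the beam height; the interlaced target is the
intersection of the four strips — a regular octagon. Its minimum caliper
width (across-flats, computed by rotating calipers over the convex polygon's
edge normals) equals the strip width, 2.0 mm, which is the natural reading
of the printed "2 mm diameter"; the across-vertices diameter,
2/cos(22.5°) ≈ 2.165 mm, is also reported. Doses (800 Gy entrance, 820 Gy
target) are carried as plan metadata only — no radiation transport is
computed. Raster renderings (beam-pass counts) support visual checks and
area/thickness cross-validation against the analytic geometry.

## Synthetic data generator

The generator emulates the statistical signature of GAERS (Genetic Absence
Epilepsy Rat from Strasbourg) recordings, not their biophysics:

* **Montage** — two symmetric rows of 5 electrodes at AP +3, +1, −1, −3,
  −5 mm and ML ±4.5 mm. The AP coordinates are chosen so that the four
  transection planes (+2, 0, −2, −4 mm) fall midway between adjacent
  left-row electrodes.
* **Background** — Gaussian 1/f^β noise (β = 1, flattened below 0.5 Hz),
  RMS 50 µV, with a shared component across channels; `coupling` is the
  shared-variance fraction, so baseline magnitude-squared coherence is
  coupling² (default coupling 0.6).
* **Seizures** — a phase-aligned stack of f0 harmonics (default 7 Hz;
  relative amplitudes 1, 0.6, 0.35, 0.2, 0.1) whose aligned phases produce
  one sharp spike per cycle. The common phase carries Ornstein-Uhlenbeck
  jitter (SD 1 rad, τ 0.3 s) pinned to zero at both ends, so bursts are
  imperfectly periodic — independent realizations decorrelate across Welch
  sub-segments — while the cycle count over a burst of duration d is exactly
  round(d·f0). Mild amplitude modulation (10%) and 0.1 s raised-cosine
  edges complete the morphology. With only the fundamental the waveform
  degenerates to a (jittered) sinusoid.
* **Events** — Poisson count at 62.2/h with truncated-normal durations
  (24.8 ± 2.7 s, truncated to [5, 60] s). Free time is partitioned into
  random inter-event gaps (normalized exponentials), i.e. positions are
  uniform order statistics conditioned on non-overlap of the 10%-margin
  analysis windows plus a 4 s gap — exact at any feasible occupancy, with a
  placement error when the rate is infeasible. Events keep ≥6.5 s from the
  session start and ≥2.5 s from its end so every event's spectral grid fits.
* **Amplitude calibration** — seizure amplitude is set so broadband
  ictal/interictal power is ≈10:1. Because SWD power concentrates near the
  fundamental while the 1/f background spreads over the whole spectrum, the
  in-band (6–8 Hz) SNR is then of order 100, as in real recordings where
  ictal activity dwarfs the background; this also makes the measured ictal
  band-power ratio track a requested `power_scale` closely.
* **Treatment effect** — on target channels (default: left hemisphere) the
  SWD component power is multiplied by `power_scale`, and a fraction
  `coherence_drop` of its variance is replaced by an independently jittered
  copy carrying a uniform random global phase (without the random phase the
  copy would stay partially correlated with the shared burst and inflate the
  mixed power), lowering inter-channel coherence. The background is
  untouched, so interictal measures are unaffected by construction.

What the generator does **not** emulate: thalamocortical dynamics, spike
asymmetry and waveform nonstationarity within a burst, distance-dependent
coherence (a single shared-component model is used), artifacts, electrode
drift, or any direct radiation physics. Passing tests therefore demonstrate
correctness and calibration of the analysis chain on data with the stated
statistical structure, not performance on raw in vivo recordings.

## Numerical choices and problem sizes

* Sampling: the acquisition default is 5 kHz, but everything analysed lives
  below 20 Hz (or 120 Hz for interictal bands), so the validation suite and
  the reproduction script generate sessions at 200–250 Hz; event statistics
  are independent of the sampling rate.
* Validation sizes: the Monte-Carlo RFT calibration uses 500 null
  replicates of 20-vs-20 smoothed maps on the 121 × 161 grid; effect
  recovery estimates the per-experiment success rate over 40 replicate
  experiments of 20 seizures per condition (40 rather than fewer because
  the rate estimator's Monte-Carlo error at smaller counts is comparable to
  the margin being tested); the null-specificity check of the band
  statistics uses 60 replicate experiments of 4 animals × 2 timepoints × 3
  seizures. Per-seizure z maps carry substantial cross-seizure variance
  from the baseline SD estimate (a 2.5 s baseline spanned by 4 s windows
  yields only ~2–3 independent samples), which is the sensitivity-limiting
  factor of the whole chain.
* Degenerate inputs: zero baseline SD raises a degenerate-baseline error
  naming the frequency; all-equal ANOVA cells return F = 0, p = 1; a
  constant trace yields no spikes; events whose analysis window leaves the
  recording are excluded, never clipped.
* Detection (used when ground truth is not available): candidates from a
  hysteresis gate on the smoothed 6–8 Hz Hilbert envelope (on/off at 5×/2.5×
  a low-quantile floor — the median would sit at the ictal level when
  seizures occupy most of a session), refined to first/last spike at 4.5
  robust SDs of the out-of-candidate background, widened by half a
  fundamental cycle (the first spike sits mid-cycle), and merged across
  channels by majority vote on a 10 ms lattice. Robust SD is 1.4826 × MAD
  throughout, since the spikes themselves inflate the plain SD.
* EDF export uses 1 s records and 16-bit quantization against a per-channel
  symmetric physical range; electrode coordinates ride in the per-signal
  transducer field. The HDF5 container is the lossless primary format.

## Known limitations

* The RFT threshold treats kernel smoothness as the field smoothness; with
  the extra intrinsic smoothness of overlapping Welch windows the test is
  conservative rather than exact.
* Fixed-effects pooling ignores animal-level variance components; with few
  animals and many seizures, population-level claims are correspondingly
  optimistic (this mirrors the analysis the pipeline reproduces).
* The as-stated between/within ANOVA layout inherits the design
  inconsistency discussed above; use `mode="within"` for the coherent
  longitudinal alternative.
* Coherence maps currently enter band summaries but not the RFT stage,
  which operates on power maps per channel.
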