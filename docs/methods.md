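# Methods

## The measurement model

A sparklet is the optical signature of Ca²⁺ influx through one (or a few
simultaneously open) plasma-membrane channels, reported by a cytosolic
biosensor. Because the biosensor signal is proportional to local sensor
expression, openings multiply the baseline: the rendered and analysed
quantity is ΔF/F₀ = (F − F₀)/F₀, which is expression-independent. The
model underlying both the simulator and the analysis is separable:

    ΔF/F₀(x, y, t) = level · q · amp(t) · exp(−r² / 2σ²)

with `q` the unitary amplitude of a single open channel, `level` the
number of simultaneously open channels (amplitudes are integer multiples
of `q` — the quantal structure that justifies the "optical patch-clamp"
reading), `amp(t)` a normalized temporal envelope, and an isotropic
Gaussian footprint. The half-max contour of the footprint encloses
2π ln2 σ², so the configured half-max area fixes σ.

The temporal envelope is a linear rise over twice the attack half-time,
an optional full-open plateau, then an exponential decay with the decay
half-time as its half-life. Only the two half-times are specified by the
reference measurements; the rise/decay shapes are this package's choice,
selected so that the measured half-times equal the configured ones
exactly in the noiseless limit.

## Simulator (the study conditions)

Defaults reproduce the stimulated (agonist/hypoxia-like) condition of
en face cerebral-artery endothelium recordings:

| parameter | default | meaning |
|---|---|---|
| `fov_px`, `pixel_um` | 512, 0.27 | field geometry (138 µm side) |
| `frame_rate_hz`, `n_frames` | 40, 1000 | 25 s recording |
| `mean_cell_area_um2` | 462 | endothelial cell area (mosaic + cells-per-FOV) |
| `unitary_dff` | 1.10 | unitary amplitude q (ΔF/F₀) |
| `attack_half_ms`, `decay_half_ms` | 87, 84 | kinetic half-times |
| `halfmax_area_um2` | 17.2 | footprint half-max area (σ ≈ 1.99 µm) |
| `site_rate_hz` | 0.13 | per-site Poisson opening rate (stimulated) |
| `sites_per_cell` | 0.108 | active-site density when `n_sites` unset |
| `max_channels_per_site`, `extra_channel_prob` | 3, 0.15 | level distribution: P(level k+1)/P(level k) |
| `baseline_mean`, `read_noise_sd` | 1000, 50 counts | EMCCD-scale baseline and read noise (50 counts = 0.05 ΔF/F₀) |
| `shot_noise`, `shot_gain` | on, 1.0 | Gaussian-approximated shot noise, var = gain·F |
| `quiescent_frames` | 10 | pre-stimulation window used to define F₀ |

Design choices:

- **Gating** is a homogeneous Poisson process per site over the
  post-baseline window; each opening's level is drawn from a truncated
  geometric distribution, and openings that overlap in time at one site
  sum in the rendering — the second route by which multi-level
  amplitudes arise. The open dwell is the deterministic rise plus an
  exponential plateau (`plateau_mean_ms`, default 0 so that the decay
  half-time measured from the peak equals the configured value). The
  recording's published mean duration (373 ms) exceeds twice the sum of
  the published mean half-times (342 ms); the two are not reconcilable
  from the definitions alone, so no reconciliation is attempted — the
  duration field is always the identity (attack + decay) × 2.
- **Cell mosaic**: a seeded nearest-neighbour (Voronoi) tessellation with
  the configured mean cell area, lognormal per-cell brightness (CV 0.15)
  and 1-px optical blur. This yields realistic per-cell normalization
  denominators without imaging tissue; it has no cell-shape statistics,
  no nuclei, no vignetting.
- **Noise**: shot noise is approximated as Gaussian with
  variance = `shot_gain`·F (accurate above ~100 counts), plus Gaussian
  read noise. No noise statistics were published for the reference
  recordings; these are stated configuration values, not inferences.
- **Sites** are placed uniformly with a 5 µm border margin (so footprints
  are fully sampled) and an 8 µm minimum pair separation (distinct,
  resolvable sites). Sites are quiescent during the first 10 frames,
  mirroring the pre-stimulation baseline period.
- **Timestamps** are generated at a constant configured rate; the
  acquisition-rate variability of real instruments (30–55 fps) is
  carried as metadata, not simulated as jitter.
- **Transient mode** adds a second, phenomenological event class
  (ER-amplified Ca²⁺ transients: same amplitude, ~60 µm² spread, ~600 ms
  decay half-time) for exercising the event classifier. No ER store
  dynamics are modelled, and very large transients spanning many ROIs
  can fragment into more than one detection; the sparklet pathway is the
  validated one.
- Determinism: gating, mosaic and noise draw from three fixed
  `SeedSequence` spawn keys of the config seed, so one seed yields
  byte-identical movies and independent stages.

## Detection

1. F₀ = pixel-wise mean of the first 10 frames; pixels with F₀ ≤ 0 are
   masked, not divided.
2. ΔF/F₀ traces are spatial means over 5.3 × 5.3 µm ROIs (20 px at
   0.27 µm) tiled with 50% overlap — a reproducible grid in place of
   hand-placed ROIs.
3. **Candidate calling** on each trace uses a sensitive threshold
   (5 × robust noise SD, floored at 0.02 ΔF/F₀). The quantal threshold is
   deliberately *not* applied to the ROI mean: averaging a 17 µm²
   footprint over a 28 µm² ROI that may be mis-centred by up to half a
   tile stride dilutes the peak to ~0.5–0.65 of its true amplitude.
   Events end at the first sub-threshold excursion sustained ≥ 2 frames;
   single-frame spikes are rejected; segments extend to the local
   baseline (never into a neighbouring event's run) so kinetics can be
   measured from the true onset.
4. **Refinement**: a 2-D Gaussian is fitted to the peak-frame pixels of
   each candidate; projecting the fitted footprint through the event's
   frames gives a per-frame amplitude on the true ΔF/F₀ scale, with
   sub-pixel position. Acceptance then applies the quantal threshold —
   default 0.5 × unitary amplitude — to this refined amplitude.
   Broad, sub-unitary fits (σ > 2.5 × expected and amplitude < 0.8 q)
   are rejected: they are superpositions of tails from simultaneously
   active neighbouring sites, not openings.
5. **Peak interpolation**: at 40 fps the sampled maximum of an 87 ms
   rise / 84 ms decay waveform underestimates the instantaneous peak by
   3–4% on average, which would consume most of the quantal tolerance
   band; a clamped quadratic interpolation through the top three samples
   recovers most of the loss. Flat-topped (plateau) events are exempt —
   their sampled maximum is the peak.
6. **Duplicates and sites**: detections from overlapping ROIs that
   coincide in time and lie within 4 µm collapse to the
   highest-amplitude copy; surviving events are single-linkage clustered
   into sites with the same radius. The radius sits between localization
   error (≪ 1 µm) and the minimum credible site separation.

## Quantal and kinetic measurement

- **Unitary amplitude**: histogram of event amplitudes (bin 0.05 ΔF/F₀),
  single Gaussian fitted to the dominant peak within ±35% of the modal
  bin; q is the fitted mean. Secondary modes (multiples) are located on
  a smoothed histogram and flagged, never mixed into the fit. Fewer than
  30 events is an error advising pooling across recordings.
- **Levels**: level = round(amplitude/q) accepted within ±0.25 q of the
  multiple. The published reporting band (1.08–1.10 "and multiples") is
  narrower than any realistic noise band and is read as the definition
  of the histogram mode; the tolerance band is configurable.
- **Kinetics**: the attack half-time runs from the event onset to the
  interpolated 50%-of-peak crossing on the final ascent; the onset is
  found by fitting a line to the mid-rise (25–75% of peak) samples and
  extrapolating to zero — exact for a linear rise and noise-averaged
  otherwise. Decay runs from the peak sample to the last 50% crossing on
  the falling side. Truncated rises (peak in the first frame, or an
  instantaneous step) and decays cut off by the recording end are
  flagged. Duration = (attack + decay) × 2 by definition, asserted
  field-wise on every event.
- **Spread**: the count of 8-connected pixels containing the peak pixel
  with ΔF/F₀ ≥ 50% of the event's refined peak amplitude, at the peak
  frame, times the pixel area. Using the refined amplitude rather than
  the raw maximum pixel avoids the upward noise bias of a max statistic.
  The half-max-at-peak-frame rule is this package's operational
  definition; the reference work does not state its contour level.
- **Classification**: events with duration > 1 s *or* spread > 50 µm²
  are transients (boundary values stay sparklets); both cutoffs are
  parameters.

## Statistics

Per-recording summaries follow the reporting conventions of the source
workflow: events/s per FOV, mean per-active-site frequency, sites per
cell (user-supplied cell count preferred; otherwise field area divided
by the 462 µm² mean cell area, floored at one cell), mean ± SEM. Group
comparisons: two-tailed Student's t-test (paired per design) for two
groups, one-way ANOVA with Šidák-adjusted pairwise post hoc p-values
(1 − (1−p)^m) for three or more; a Shapiro–Wilk screen switches to
Wilcoxon / Mann–Whitney / Kruskal–Wallis when normality fails.

Note on rate validation: the mean frequency over *active* sites is
biased upward at low rates (conditioning on ≥ 1 event), so recovery
checks against a Poisson oracle pool total detected events over all
configured sites and seeds.

## Validation problem sizes

Recovery tests use 96–256 px fields, 200–800 frames, and 3–50 seeds per
property; the amplitude-mode check pools ~20 fields, and rate recovery
pools 50 recordings of 4 sites at 0.10 Hz. These sizes give the Poisson
and histogram checks enough events for their exact intervals while
keeping the suite quick to run.

## What passing tests do and do not show

The simulator shares its separable signal model with the analysis, so
recovery tests validate the *implementation* of the definitions — not
their adequacy for real tissue. Real recordings add photobleaching,
motion, focus drift, non-Gaussian EMCCD noise, heterogeneous sensor
kinetics and overlapping ER-driven signals, none of which are simulated.
Precision/recall and parameter-recovery figures reported by the
acceptance script are therefore upper bounds on real-data performance.

## Known limitations

- Event amplitudes below half the unitary amplitude are undetectable by
  design (sub-quantal events are treated as noise).
- Two sites closer than the merge radius (4 µm) are indistinguishable;
  simultaneous openings at sites ~8–12 µm apart can still shift fitted
  positions slightly.
- The Gaussian-footprint fit assumes one dominant source per ROI window;
  very large transients spanning several windows may fragment.
- Kinetic half-times carry a ≤ one-frame-interval sampling bias
  (decay slightly long, attack slightly short at 40 fps).
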