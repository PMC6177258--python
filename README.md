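# sparklet

Quantitative analysis of **Ca²⁺ sparklets** — the localized, transient
fluorescence events produced by Ca²⁺ influx through single plasma-membrane
channels (e.g., TRPA1) in the endothelium of intact arteries expressing a
genetically encoded Ca²⁺ biosensor (GCaMP6f). The package implements the
*optical patch-clamp* workflow: single-channel gating is inferred from
fluorescence movies instead of electrical recordings, by resolving quantal
amplitude levels, open-time kinetics and spatial spread of each event.

It is written for researchers analysing en face endothelial Ca²⁺ imaging
(or any wide-field recording of point-source channel activity) who need a
reproducible, scriptable alternative to interactive spark-analysis tools —
and a simulator that generates movies with known ground truth so every
stage of the analysis can be validated.

## What it computes

For a movie `F(x, y, t)`:

- **Baseline** `F₀` = pixel-wise mean of the first 10 pre-stimulation
  frames; **ΔF/F₀** = (F − F₀)/F₀.
- **Events**: supra-threshold excursions of ΔF/F₀ traces from
  5.3 × 5.3 µm regions of interest tiled over the field with 50% overlap;
  each candidate is refined by a 2-D Gaussian fit to the pixel data, and
  accepted if its amplitude exceeds half the unitary amplitude.
- **Quantal levels**: the unitary amplitude *q* is the mode of a Gaussian
  fitted to the dominant peak of the population amplitude histogram
  (bin width 0.05 ΔF/F₀); an event's level is `round(amplitude / q)`
  within a tolerance band — the number of simultaneously open channels.
- **Kinetics**: attack = half-time from event onset to peak; decay =
  half-time from peak to dissipation; duration = (attack + decay) × 2.
- **Spatial spread**: area of the contiguous region ≥ 50% of the event's
  peak ΔF/F₀ at the peak frame.
- **Recording statistics**: events/s per field of view, active sites,
  sites per cell (cell count supplied, or field area / 462 µm² mean
  endothelial-cell area), per-site frequency; mean ± SEM, Student's
  t-tests, one-way ANOVA with Šidák post hoc comparisons.
- **Vascular metrics**: myogenic tone = [1 − active/passive] × 100;
  dilation as % of tone reversed; percent hemisphere infarcted
  %HI = (V_C − V_L)/V_C × 100 from slice-wise normal-tissue volumes;
  Z-profile AUC; per-cell DHE F/F₀ time courses.

The simulator renders each channel opening as
`ΔF/F₀(x, y, t) = level · q · amp(t) · G(x, y)` on a Voronoi cell mosaic:
a linear rise and exponential decay parameterised by half-times, and an
isotropic Gaussian footprint whose half-max contour encloses a configured
area (17.2 µm² default, so σ = √(area / 2π ln 2)). Gating is a
homogeneous Poisson process per site; a JSON sidecar records every true
opening for recovery tests.

## Worked example

```python
import sparklet as sp

cfg = sp.SimConfig(fov_px=128, n_frames=400, frame_rate_hz=40,
                   n_sites=4, site_rate_hz=0.3, seed=1)
movie, truth = sp.simulate_movie(cfg)       # 128x128 px, 10 s recording
det = sp.detect_movie(movie)                # detect + refine events
table, hist, events = sp.analyze_detection(det)
m = sp.match_events(truth, det.events)
print(f"{len(det.events)} events at {len(det.sites)} sites, "
      f"recall {m.recall:.2f}")
print(table[['amplitude_dff', 'level', 'attack_ms', 'decay_ms',
             'spread_um2']].round(2).head(3))
```

prints

```
13 events at 4 sites, recall 1.00
   amplitude_dff  level  attack_ms  decay_ms  spread_um2
0           1.07    1.0      83.94     90.89       17.20
1           1.05    1.0      81.46     84.26       16.77
2           1.09    1.0      84.77     82.98       16.99
```

i.e. thirteen events were detected, all true openings recovered; each row
is one event with its peak amplitude (unitary ≈ 1.1 ΔF/F₀ ⇒ one open
channel), half-time kinetics near the configured 87/84 ms, and a half-max
footprint near the configured 17.2 µm².

The same pipeline runs from the shell:

```bash
sparklet simulate --config sim.yaml --out movie.tif --truth truth.json
sparklet analyze  --movie movie.tif --out-events events.csv --out-summary fov.json
sparklet vessel   --active-um 80 --passive-um 100   # myogenic tone: 20%
```

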