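# wavepatt

Detection and analysis of propagating wave patterns — plane waves,
synchrony, sources, sinks, spirals and saddles — in gridded neural
recordings (multi-electrode LFP arrays, optical voltage imaging), via
velocity vector fields.

The pipeline:

1. **Recording I/O & preprocessing** — load 4D `(row, col, time, trial)`
   arrays from NPZ/NPY/HDF5/MAT containers, interpolate bad channels,
   z-score or baseline-subtract, check sampling adequacy, spatially
   down-sample or smooth (`wavepatt.recording`).
2. **Oscillation filtering** — analytic signal (amplitude + phase) per band
   via zero-phase 8th-order Butterworth + Hilbert, or complex Morlet
   wavelet (`wavepatt.filtering`).
3. **Optical flow** — velocity fields `(u, v)` between consecutive frames
   by minimizing a Charbonnier-penalized data-constancy + smoothness
   functional; fixed-point iteration on the Euler–Lagrange equations with
   exact sparse inner solves and circular derivatives for phase data
   (`wavepatt.flow`).
4. **Pattern detection** — critical points at sub-grid resolution
   (bilinear zero-contour intersection), Jacobian classification
   (node/focus/saddle, stable/unstable), winding-number pattern extents,
   and the global order parameters φ (plane waves) and R (synchrony)
   (`wavepatt.detection`).
5. **Tracking & transitions** — temporal linking into persistent pattern
   instances with duration/extent/displacement gates, observed-vs-expected
   transition counts under a random-times null, Bonferroni-corrected
   paired tests (`wavepatt.tracking`).
6. **Vector-field SVD** — real (`[u | v]`) and complex (`u + iv`)
   decompositions into spatiotemporal modes with variance fractions and
   automatic mode classification (`wavepatt.decomposition`).
7. **Synthetic data** — ground-truth generators for drifting
   source/sink/spiral/saddle/plane-wave patterns, site-matched white-noise
   surrogates, randomized detection-accuracy benchmarks
   (`wavepatt.simulate`).

## CLI

```bash
# full pipeline from a YAML config
wavepatt run -c config.yaml -o results/

# generate a synthetic dataset + ground-truth tracks
wavepatt simulate -c sim.yaml -o data.npz

# score detections against ground truth
wavepatt evaluate --truth data.truth.csv --detected results/critical_points.csv

# compare against white-noise surrogates
wavepatt surrogate -c config.yaml -n 100 -o surrogate_summary.csv
```

Example config (synthetic input; for file input use `input: {path, fs,
layout}` and a `filter:` block instead):

```yaml
simulation:
  grid: [14, 14]
  n_steps: 60
  patterns:
    - {ptype: source_sink, x0: 6.5, y0: 6.5, c: 4.0}
  noise_sigma_rel: 0.0
  seed: 7
signal: phase          # phase | amplitude | raw
flow: {alpha: 0.5, beta: 10.0}
detect: {Tpw: 0.85, Tsyn: 0.8, Ledge: 2.0, Lradius: 2.0}
track: {Ldisp: 0.5, tgap: 1, tdur: 5}
```

Python API:

```python
from wavepatt import run_pipeline

bundle = run_pipeline({"simulation": {...}, "signal": "phase"})
bundle.patterns          # tracked pattern instances (DataFrame)
bundle.critical_points   # per-frame detections
bundle.order_params      # phi(t), R(t)
bundle.svd_modes         # dominant spatiotemporal modes
bundle.save("results/")
```

## Conventions

- Canonical axis order `(row, col, time, trial)`; `x` is the column
  coordinate, `y` the row coordinate; velocities are in grid spaces per
  time step.
- Phase maps live in (−π, π]; all derivatives on phase data use circular
  subtraction.
- Stability labels follow the dynamical-systems convention (stable ⟺
  trace < 0, attracting flow), so sources are unstable nodes and sinks
  stable nodes; pass `stability_convention="inverted"` to flip.
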