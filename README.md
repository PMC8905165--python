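# motortrace

Single-molecule TIRF motility analysis for processive kinesin motors, with
a paired generative simulator so every estimator can be validated by
parameter recovery — no experimental recordings required.

The package targets the standard *in vitro* reconstitution workflow used to
characterize motors such as CENP-E (kinesin-7) and kinesin-1: fluorescently
tagged motors land on immobilized GMPCPP microtubules, movies are recorded
by TIRF microscopy, kymographs are drawn along each microtubule, and
per-motor motility events are measured and summarized.

## What it computes

For an event set (from tracking or from simulator ground truth):

- **Velocity** — whole-run speed |Δx|/Δt, pauses included; histograms at
  20 nm/s bins fitted by least squares with one Gaussian or, for
  heterogeneous populations, two Gaussians (means ± s.e.m. from the fit
  covariance, r²).
- **Run length and residency time** — summarized as the decay constant τ of
  A·exp(−x/τ) fitted to the empirical survival curve 1 − ECDF, with a
  percentile-bootstrap or Wald 95% CI.
- **Landing rate** — events·µm⁻¹·min⁻¹ per microtubule, mean ± s.e.m. over
  microtubules; total and processive-only, compared between constructs with
  Welch's t-test.
- **Motile fraction** — fraction of binding events that move processively
  (net displacement ≥ 2 px with ≥ 80% directional consistency), with a
  Wilson 95% interval. Events shorter than five frames are excluded.
- **Photobleaching** — 4×4 px ROI traces with 10×10-minus-ROI background
  correction, initial intensity over the first five frames, MAD-based
  aggregate exclusion, and automated counting of downward bleaching steps
  by penalized change-point segmentation.

The simulator (`motortrace.sim`) generates the matching ground truth:
homogeneous Poisson landings along each microtubule, Gaussian-mixture
per-motor speeds, exponential run lengths (per-distance detachment) or
residencies (per-time detachment), two-state pausing, exponential
photobleaching of 1–8 fluorophores, and rendered 16-bit movies with a
Gaussian PSF, shot noise and read noise. Five construct configurations
(`cenpe483`, `cenpe483lz`, `cenpe754`, `cenpefl`, `k560`) are packaged
with calibrated parameters.

## Worked example

Simulate the CENP-E_754 construct (truth tables only) and analyze it:

```bash
motortrace simulate src/motortrace/configs/cenpe754.yaml \
    --out demo --seed 11 --no-render
# simulated cenpe754: 100 microtubules, 796 landings (seed 11)

motortrace analyze demo/truth_frames.csv --truth-mode \
    --construct cenpe754 --field demo/field.csv --duration-min 2.0 \
    --out demo/report.json
```

The JSON report for this run contains (abridged):

```
n_events_raw        765      # landings with >= 1 imaged frame
n_events_filtered   561      # after the >= 5-frame filter
velocity_fit        mean 177.2 ± 2.4 nm/s (r² = 0.958)
run_length_fit      tau = 629.3 nm, CI95 [549.2, 719.2]
residency_fit       tau = 4.03 s
landing_rate_total  0.378 ± 0.012 events µm⁻¹ min⁻¹
motile_fraction     0.437, Wilson CI95 [0.396, 0.478]
```

The fitted velocity recovers the generative 180 nm/s and the landing rate
its generative 0.392 µm⁻¹ min⁻¹ within sampling error. The run-length and
residency constants come out *below* their generative scales (703.3 nm,
5.3 s): in a two-minute movie long runs are right-censored, sub-five-frame
events are discarded, and static binders enter the event mix — exactly the
biases a real recording carries. The estimators themselves are validated on
uncensored fixtures at the calibrated sample sizes (see below and
`docs/methods.md`).

`motortrace simulate` without `--no-render` also writes the TIFF movie and
per-microtubule kymographs; `motortrace bleach movie.tiff points.csv --out
dir/` runs the photobleaching pipeline; `motortrace report report.json
--out plots/` renders the histogram and survival-curve figures.

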