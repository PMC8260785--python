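# rampfix

Analysis of how spontaneous saccades are generated, built for calcium-imaging
experiments in larval zebrafish making self-initiated eye movements in the
dark.  The package covers the full chain from raw measurements to the
ramp-to-threshold account of saccade timing:

* **behavior** — saccade detection from eye-position traces (median filter,
  velocity threshold `max(mean|v| + 3·SD(v), 10°/s)`, 1.4-s artifact rule),
  fixation segmentation, and summary statistics (fixation-duration quantiles,
  same-direction transition fraction, amplitude medians, position PSD).
* **imaging_preproc** — Fourier cross-correlation frame registration with a
  median + 5·MAD corrupted-frame rule, nuclei detection on time-averaged
  images (morphological opening, regional maxima, 144-px² area cap),
  exponential-decay (τ) fitting for the calcium kernel, and 3D affine point
  registration.
* **sta_analysis** — saccade-triggered averages (STAs) on a 31-bin, ±5-s grid,
  one-way-ANOVA screening of eye-movement responsive cells with
  Holm–Bonferroni correction, PCA of L2-normalized STAs with the spherical
  (Φ, Θ) functional map, Φ-binned population averages, and silhouette-selected
  K-means clustering.
* **sr_analysis** — selection of pre-saccadic rise (SR) cells by one-sided
  Spearman correlation with time to the upcoming saccade, rise-onset and
  ramp-slope measurement, choice probability (ROC area) for decoding upcoming
  saccade direction, the ramp-to-threshold predictor, and ideal-observer
  baselines.
* **ablation_analysis** — equal-sample resampled effect sizes for fixation
  duration after laser ablations, cylindrical fraction-ablated estimates,
  bootstrap effect-vs-fraction correlations, and targeted-group comparisons
  against sham.
* **synthetic_data** — generators that emulate the behavioral and calcium
  statistics of the experiment with known ground truth, so every stage runs
  and is tested without any data download.

## The model

An SR cell's deconvolved activity ramps linearly within a fixation,
`y(t) = D·t` from its rise onset, and a saccade is triggered when the
population signal reaches a fixed bound κ, so the rise time satisfies
`κ = D·t_r`.  Online prediction uses a running slope estimate
`D̃(t) = median` of the activity derivatives since the detected population
rise onset, giving a predicted time-to-saccade `t̃_r(t) − t = κ/D̃(t) − t`.
Under this model, slower ramps start earlier and rise longer — slope and
rise duration are inversely related at fixed κ — which the synthetic SR
generator reproduces by construction and the estimators recover.

## Worked example

```python
import numpy as np
from rampfix.behavior import behavior_summary, detect_saccades, segment_fixations
from rampfix.synthetic_data import (BehaviorConfig, gen_eye_trace,
                                    gen_population_rise_traces)
from rampfix.sr_analysis import (RampModel, derivative_threshold_from_slopes,
                                 evaluate_ramp_model, ramp_predict)

# one hour of simulated spontaneous eye movements
cfg = BehaviorConfig(duration_s=3600.0, seed=42)
trace, truth = gen_eye_trace(cfg)
events = detect_saccades(trace)
stats = behavior_summary(events, segment_fixations(events, trace), trace)
print(f"saccades: {stats['n_saccades']}")
print(f"median fixation duration: {stats['fixation_median_s']:.1f} s")
print(f"same-direction fraction: {stats['same_direction_fraction']:.3f}")

# ramp-to-threshold prediction on population activity at 18 fixation durations
durations = np.arange(3.5, 21.0, 1.0)
pops, slopes = {}, []
for i, d in enumerate(durations):
    traces, s = gen_population_rise_traces(d, 200, seed=100 + i)
    pops[d] = traces.mean(axis=0)
    slopes.append(s)
model = RampModel(kappa=1.0,
                  derivative_threshold=derivative_threshold_from_slopes(
                      np.concatenate(slopes)))
preds, acts = [], []
for d in durations:
    rp = ramp_predict(pops[d], model)
    preds.append(rp.predicted_remaining_s)
    acts.append(rp.actual_remaining_s)
cc, err = evaluate_ramp_model(np.concatenate(preds), np.concatenate(acts))
print(f"prediction vs actual time-to-saccade: cc = {cc:.2f}")
```

prints

```
saccades: 257
median fixation duration: 11.5 s
same-direction fraction: 0.230
prediction vs actual time-to-saccade: cc = 0.93
```

The detected behavior matches the generator's configured statistics (median
fixation ≈ 11.4 s, 23% same-direction repeats), and the online ramp model's
predicted times-to-saccade correlate strongly with the actual times across
fixation durations from 3.5 to 20.5 s.

A command-line interface wraps the same functions:

```sh
rampfix simulate --seed 1 --duration 900 --out sim/
rampfix behavior --eye sim/eye_left.csv --out events.csv --summary summary.json
rampfix sr --cells sim/cells.npz --events events.csv --out sr_out/
```

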