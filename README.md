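# motionmask

Opponent motion-energy modelling and "invisible noise" masking analysis for
visual neuroscience.

Both standard accounts of early motion detection — the Reichardt detector
of insect vision and the motion energy model of mammalian vision — filter a
stimulus with two spatial and two temporal linear filters, apply a
nonlinearity, and subtract oppositely-tuned terms (*opponency*).  With
shared separable filters the two circuits are mathematically identical (up
to a factor of 4).  Because the circuit is nonlinear, frequency components
of a stimulus interact: a noise grating at a spatial frequency the detector
*cannot see on its own* can still shift and destabilise the response to a
visible moving signal.  Whether this happens depends entirely on the
front-end spatial filters:

* **bandpass front ends** (mammals: derivative-of-Gaussian filters in a
  quadrature-like pair) — invisible components cannot interact with visible
  ones, and the masking function measured with noise reproduces the
  detector's sensitivity;
* **lowpass front ends** (insects: the Gaussian angular sensitivity of an
  ommatidium, sampled at two positions Δx apart) — low-frequency noise is
  transmitted by the filters, cancelled only at the opponency stage, and
  its surviving interaction terms mask visible signals far below the
  sensitivity band.  Masking becomes *lowpass* while sensitivity stays
  *bandpass*, as observed in the optomotor response of the praying mantis.

This package implements, with tests against closed-form oracles:

- the filter banks and their frequency responses (`motionmask.filters`);
- opponent energy via both circuits plus the closed-form mean response to
  single gratings, `C² G sin(φ_S2−φ_S1) sin(φ_T1−φ_T2)`, and the
  cross-component interaction terms of compound stimuli
  (`motionmask.motion_model`);
- the experiment's masked-grating stimulus with the close-viewing angular
  correction `θ(x) = atan(x/RD)` and Butterworth windowing
  (`motionmask.stimulus`);
- Monte-Carlo direction-discrimination on arrays of detectors: response
  rates, 90 %-correct thresholds, sensitivity and masking functions
  (`motionmask.simulation`);
- behavioural trial analysis: response rates, masking rate
  `M = (R₀ − R)/R₀` with exact binomial CIs, and fits of
  `M(f) = a − exp(b·log f − c)` (`motionmask.behavior_analysis`);
- synthetic optomotor trial datasets with known ground truth, replicating
  the 44-condition design (`motionmask.synthetic_data`).

## Worked example

Simulate masking of a weak drifting grating (0.0185 cpd, 8 Hz) by
phase-randomised noise at three spatial frequencies, using the insect-style
detector array:

```python
import numpy as np
from motionmask import (GratingComponent, insect_model, masking_function,
                        sensitivity_curve, insect_bank)
from motionmask.simulation import INSECT_SIM_SIGNAL_CONTRAST

model = insect_model()                      # 10 detectors, calibrated
signal = GratingComponent(contrast=INSECT_SIM_SIGNAL_CONTRAST,
                          f_s=0.0185, f_t=8.0, direction=+1)
curve = masking_function("insect-rate", signal, noise_amplitude=0.198,
                         noise_frequencies=[0.0025, 0.03, 0.3],
                         array=model, n_presentations=300, seed=0)
sens = sensitivity_curve(insect_bank(), np.array([0.0025, 0.03, 0.3]))
print(f"model tuned to {model.optimum[0]:.3f} cpd")
for f, m, lo, hi, s in zip(curve.noise_frequencies, curve.values,
                           curve.ci_low, curve.ci_high, sens):
    print(f"noise {f:>6.4f} cpd: masking rate M = {m:.2f} "
          f"[{lo:.2f}, {hi:.2f}], sensitivity {s:.3f}")
```

prints

```
model tuned to 0.037 cpd
noise 0.0025 cpd: masking rate M = 0.41 [0.35, 0.47], sensitivity 0.116
noise 0.0300 cpd: masking rate M = 0.50 [0.44, 0.56], sensitivity 1.000
noise 0.3000 cpd: masking rate M = 0.00 [0.00, 0.01], sensitivity 0.000
```

Read the two rightmost columns together: at 0.0025 cpd the model's own
sensitivity is ~12 % of peak — a grating there is nearly invisible to it —
yet such noise masks the visible signal almost as strongly as noise placed
at the sensitivity peak (M = 0.41 vs 0.50, the bracketed values are 95 %
binomial confidence intervals).  At 0.3 cpd, above the band, masking
vanishes.  Running the same experiment with the mammal-style bank
(`masking_function("mammal-threshold", ...)`) instead yields a *bandpass*
masking function that tracks the sensitivity curve.

A command-line interface mirrors the library: `motionmask filters
describe`, `motionmask render`, `motionmask simulate sensitivity|masking`,
`motionmask synth` and `motionmask analyze` (see `--help` on each).

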