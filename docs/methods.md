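# Methods

## The model

A single opponent motion detector is a linear–nonlinear cascade: the
stimulus `s(x, t)` is projected onto two spatial kernels `SF1`, `SF2`, each
result is passed through two temporal filters `TF1`, `TF2`, giving four
separable responses `A = TF1(SF1·s)`, `A′ = TF2(SF1·s)`, `B = TF1(SF2·s)`,
`B′ = TF2(SF2·s)`, and the direction-signed *opponent energy* is formed
either as the energy-model difference
`(A+B′)² + (A′−B)² − (A−B′)² − (A′+B)²` or the Reichardt product
`AB′ − BA′`.  The two are algebraically identical up to a factor of 4, which
the test suite asserts at machine precision; everything downstream uses the
Reichardt form.

For a drifting sinusoid of contrast `C`, spatial frequency `f_S` and
temporal frequency `f_T`, the time-averaged output has the closed form

    C² · G_S1 G_S2 G_T1 G_T2 · sin(φ_S2 − φ_S1) · sin(φ_T1 − φ_T2)

where `G`/`φ` are the filter gains and phases at the stimulus frequencies.
For a sum of gratings, each pair of components with the *same temporal
frequency* additionally contributes a constant cross term

    C_j C_k · G_S1j G_S2k G_T1 G_T2 · sin(β_j − β_k + φ_S1j − φ_S2k) · sin(φ_T2 − φ_T1)

while pairs at different temporal frequencies oscillate and vanish in the
time average.  The cross term is the scientific crux: a component with
`φ_S1 = φ_S2` and high gains produces *no* solo response (the first sine is
zero in the solo formula) yet interacts with a visible component — masking
by invisible noise.  Whether such components exist depends on the spatial
filters: for an offset-Gaussian pair the phase difference `2π f_S Δx`
vanishes as `f_S → 0` while the gains stay high (interaction survives); for
Gaussian-derivative pairs the phase difference is a constant `π/2` and the
gains themselves gate both solo response and interaction (no invisible
masking).

### Phase conventions

Spatial phase is defined as the phase advance imparted on a rightward
spatial sinusoid, `φ_S(f) = 2π f · centre_offset` (equal to the angle of
the conjugate Fourier transform of the kernel); temporal phase is the angle
of the Laplace transform at `s = i2πf`.  Under exactly these conventions
the closed forms above agree sign-for-sign with causal numerical
convolution — the equivalence tests depend on it.  Phase differences are
always evaluated through complex products, so wrapping never touches the
closed forms.  Gratings carry a signed drift: a component with direction
`d` has luminance `C sin(2π(f_T t + d f_S x) + β)`.

## Filter banks

| parameter | insect bank | mammal bank |
|---|---|---|
| spatial family | offset Gaussians | Gaussian derivatives (orders 2, 3) |
| σ | 2.56° | 0.08° |
| spatial offset Δx | 4° | — |
| temporal family | lowpass / (δ − lowpass) | gamma-difference, orders n = 3, 5 |
| time constants | τ_L = 13 ms, τ_H = 40 ms | rate k = 105 s⁻¹ |

The gamma-difference kernel is `(kt)^n e^{−kt} (1/n! − (kt)²/(n+2)!)`,
a zero-DC biphasic kernel; with `k = 105 s⁻¹` its temporal peak falls in
the 5–10 Hz range typical of human motion channels.  Spatial filters are
normalised to unit DC gain (Gaussians) and unit peak gain (derivatives);
temporal responses follow the Laplace transform unscaled (a lowpass has DC
gain τ).  Absolute per-filter scale is a free convention because the whole
detector array is normalised (below).  The insect closed-form sensitivity
`exp(−4π²σ²f²)·sin(2πfΔx)` peaks at 0.037 cpd with these parameters,
slightly above the 0.03 cpd the organism itself prefers; we report our
computed peak and do not force agreement.  The mammal sensitivity peaks at
`sqrt(5/2)/(2πσ) ≈ 3.15` cpd.

## Stimulus

The behavioural stimulus is rendered directly on a uniform angular grid
(0.01°/sample) as

    I(θ, j) = 0.5 + w(x(θ)) · [A_s cos(2π(f_s θ + d f_t t)) + A_n cos(2π(f_n θ + φ_j))]

with `t = j/85` s, per-frame noise phases `φ_j` uniform on [0, 1) (the
noise is temporally broadband up to the 42.5 Hz Nyquist and carries no net
motion), and the Butterworth window `w(x) = 1/(1 + (2|x|/512)^20)`
evaluated at the pixel position `x(θ) = R·D·tan θ` of each angular sample
(R = 1600 px / 40.4 cm, D = 7 cm; the full screen subtends 142°, the
window's FWHM 85°).  Rendering in angle makes the grating period uniform in
degrees by construction — the purpose of the `atan` correction for a
subject sitting 7 cm from the screen.  Default contrasts `A_s = 0.125`,
`A_n = 0.198` keep luminance inside [0, 1]; out-of-gamut parameter choices
are clipped with a warning recorded in the movie metadata.  Model-space
stimuli (mammalian simulations, which use RMS contrasts √2 and 20√2, i.e.
amplitudes 2 and 40) are rendered without the mean-luminance offset or
gamut policing; a sinusoid of RMS contrast c is taken to have Michelson
amplitude c√2.

## Numerical realisation

Space is sampled at 0.01°, time at 1/85 s (the frame rate).  Temporal
kernels are *bin-integrated*: each discrete weight is the exact integral of
the continuous kernel over one sample bin (closed forms via exponentials
and regularised incomplete gamma functions); the Dirac impulse contributes
area 1 to the first bin.  Kernels are truncated where the remaining tail
area is below 1e−6 of the total.  Bin integration matters: τ_L = 13 ms is
barely more than one sample, and point-sampled kernels misstate the 8 Hz
gain by ~50 % where bin-integrated ones are within ~1.5 %.

Two transfer-function views are exposed: the continuous closed forms, and
the discrete transform of the sampled kernels actually convolved
(`temporal_transfer_sampled`).  Oracle tests compare the simulation against
the latter; the two agree within a few percent below 10 Hz and drift apart
(up to ~10 % by 20 Hz) exactly as coarse sampling predicts.

Presentations start cold: the convolution history is empty at stimulus
onset, and outputs are averaged over the full presentation including the
onset transient, matching an abrupt 1-s presentation.  For oracle
comparisons a `periodic` warm-up primes the filters with the end of the
(periodic) stimulus, yielding the exact steady state; with it, numeric and
closed-form means agree to ~1e−6 relative.  The cold-onset transient
biases 1-s full-window averages by ~3 % (insect) to ~6.5 % (mammal) —
a real property of abrupt presentations, which is why steady-state
validation and cold-onset simulation are kept distinct rather than hiding
one inside the other.

## Simulation procedure

Ten identical detectors (configurable) are placed on the virtual retina —
insect: evenly over the central 40° (well inside the 85° window); mammal:
over 4° on a small un-windowed field.  Results are insensitive to detector
count (10 vs 30 tested).  Outputs are summed, averaged over the
presentation, and divided by a calibration constant: the signed pooled
response to an unwindowed unit-contrast grating at the bank's optimal
frequencies drifting in the +1 direction, so that grating scores exactly +1
and its reversal −1.  A two-sided threshold T turns the pooled scalar into
a ternary judgment (+1 / 0 / −1, boundaries map to 0); sub-threshold and
wrong-direction judgments both count as incorrect.

Per presentation, fresh noise phases are drawn from per-presentation
substreams of a master seed (fixed seed ⇒ bit-identical results).  Because
the detectors are linear up to the opponency stage, each presentation is
evaluated algebraically: the signal projection onto every kernel is
precomputed once, and the noise enters through two scalars per kernel (the
in-phase and quadrature noise-pattern projections) weighted by the random
per-frame phases.  The fast path is exact for unclipped stimuli and is
asserted against the rendered-movie route in the tests.

**Insect masking experiment** — signal 0.0185 cpd at 8 Hz, decision
threshold T = 0 (pure sign rule), 500 presentations per noise frequency by
default (tests and the acceptance run use 300); masking rate
`M = (R₀ − R)/R₀` against the deterministic no-noise baseline, with 95 %
Clopper–Pearson intervals on R propagated to M at fixed R₀.  The simulated
signal contrast defaults to 0.0125 — a tenth of the behavioural display
contrast.  The choice is forced by the model's nature: it has no internal
response variability, so at the behavioural contrast the pooled output
never changes sign under any admissible noise and masking cannot register
at all; placing the simulated signal near its stimulus-noise-limited
threshold is what lets stimulus noise play the role that stimulus-plus-
internal noise plays in the animal.  With a deterministic baseline the
sign rule also caps simulated masking near 0.5 (the output is roughly
symmetric about a small positive mean), so simulated masking curves should
be read for their *shape* across noise frequency, not their absolute scale.
Two mechanisms drive the spread: the signal×noise cross term (survives as
`f_n → 0`) and the noise's own fluctuating opponent energy (suppressed at
low `f_n` by its `sin(2πf_nΔx)` phase factor); their sum gives lowpass
masking that falls to zero above ~0.1 cpd while sensitivity is bandpass —
the dissociation the package exists to demonstrate.

**Mammalian masking experiment** — signal 3 cpd at 8 Hz (RMS contrast √2),
noise RMS 20√2, 11 log-spaced noise frequencies spanning 0.3–30 cpd,
≥100 one-second presentations per point.  Noise leaves the mean pooled
output untouched but inflates its spread, most strongly when its frequency
matches the signal's.  The 90 %-correct decision threshold is the largest T
with `decide(x) = d` on 90 % of presentations, i.e. the 10th percentile of
the pooled-output sample (deterministic given the sample; a non-positive
percentile means the criterion is unattainable and the threshold is
censored).  That percentile is a *margin* that shrinks as noise widens the
distribution, so the masking function is reported as the elevation
`T₀ / T(f_n)` — the factor by which noise erodes the noise-free margin.
It is ≥ 1, peaks at the signal frequency, and rank-correlates with the
sensitivity curve (ρ ≈ 0.96 on the default grid), which is the operational
content of "the masking function approximates the sensitivity" for bandpass
front ends.  (A ratio oriented the other way, `T(f_n)/T₀`, would be ≤ 1 and
anti-correlated with sensitivity under this threshold definition; the
elevation orientation matches how threshold-elevation masking functions are
plotted in the psychophysical literature.)

## Synthetic behavioural data

The generator replicates the experiment's design: 4 signal frequencies
(0.0185, 0.0376, 0.0885, 0.177 cpd), each unmasked and with noise at 10
log-spaced frequencies in 0.0012–0.5 cpd (44 conditions), equal left/right
trials per condition (default 15 per direction; the true per-condition
counts are not published), individuals assigned round-robin (default 11).
Per condition a categorical (match / opposite / no-response) distribution
is sampled; truth tables come either from an explicit masking function or
from the insect simulation, with a lapse parameter
(`p_match = (1−lapse)·rate`, `p_none = lapse`) whose default 0.4 emulates
the observed ~60 % baseline response rate.  The masking rate is invariant
to the lapse — it cancels in `(R₀−R)/R₀` — so a deterministic simulation
with a no-noise rate of 1 can stand in for an animal with a 0.6 baseline.

What the generator deliberately does not emulate: per-individual
differences, sequential effects, observer coding errors, and asymmetric
left/right biases.  Passing end-to-end tests therefore shows the *analysis*
is correct and calibrated for ideal-ised balanced data, not that real
mantis data would satisfy the binomial assumptions exactly.

## Analysis choices

Confidence intervals are exact Clopper–Pearson (appropriate at ~30 trials
per condition; mildly conservative).  CI propagation to M holds the
baseline fixed, matching per-point error bars; consequently end-to-end
coverage sits slightly below nominal unless baselines are oversampled
(measured: 92 % at equal counts, 95.7 % with 4× baselines, over 50 seeds ×
40 conditions).  The masking-curve model `M(f) = a − exp(b·log f − c)`
(natural log, f in cpd) is a low-frequency plateau `a` with a fall-off
positioned by `c/b`; it is fit by bounded trust-region least squares from
three fixed starting points, deterministically, on untransformed M.

## Problem sizes and tolerances

Oracle grids: 5×5 (f_S × f_T) per bank, integer temporal frequencies so
product terms average to exactly zero over 1 s; agreement asserted at 2 %
(achieved ~1e−6 in steady state).  Monte-Carlo sizes: 300 presentations per
insect point, 120–150 per mammalian point — binomial/variance error at
these sizes is well inside every asserted band, and the full test suite
runs in a few seconds.  Stochastic acceptance bands are regression values
pinned from this package's own fixed-seed runs.

## Known limitations

- No gain control, no ON/OFF half-wave channels, no photoreceptor
  adaptation: the detector is the textbook separable opponent circuit.
- The deterministic decision stage has no internal noise, with the two
  consequences documented above (near-threshold simulated contrast;
  masking-rate ceiling of ~0.5).
- Spatial pooling across detectors partially averages out cross-frequency
  interactions when the signal–noise frequency difference spans cycles
  across the array; the 40° span keeps this mild for the 0.0185 cpd signal
  but masking of much higher-frequency signals by very low-frequency noise
  is under-predicted relative to the behavioural reports.
- One spatial dimension only; no gamma correction or display nonlinearity.
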