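# visuotrack

Optimal-control analysis of human visuomotor compensatory tracking.

In a compensatory tracking task a subject moves a manipulandum to keep a
displayed cursor centered while software perturbs the cursor's velocity with
band-limited Gaussian noise: `de/dt = u + d`, where `e` is the displayed
error, `u` the subject's input, and `d` the perturbation.  A long-standing
question in the study of aging is whether older adults' slower corrections
reflect a longer response *latency* or slower *post-onset* dynamics — and
whether that slowing is itself an optimal adaptation to increased internal
noise.

This package implements the full analysis chain for that question, for
researchers in computational sensorimotor neuroscience:

* **Subject model.**  Each subject is an LQG-optimal controller for a
  9-state plant (cursor integrator, perturbation prefilter, second-order
  endogenous-noise prefilter, 4th-order Pade latency, effort
  differentiator), minimizing `E[rho (d u_ideal/dt)^2 + e^2]`.  Four
  parameters describe a subject: latency `tau`, endogenous-noise intensity
  and bandwidth, and `rho`, a combined control-cost/multiplicative-noise
  weight.  The controller is `xhat' = (A - BK - LC) xhat + L y`,
  `u_ideal = -K xhat`, with `K` and `L` from the control and filtering
  Riccati equations.
* **Synthetic cohorts.**  No human recordings are distributed, so the
  package simulates the exact protocol (ten 60-s trials at 100 Hz, first
  9 s discarded, identical perturbations across subjects, first two trials
  treated as practice) with cohort parameters drawn from published log10
  statistics for young and elderly groups — every stage is validated by
  parameter recovery against known ground truth.
* **Model-free latency** by whitened cross-correlation of perturbation and
  response: onset of the corrective trend via the second derivative of the
  smoothed cross-correlation.
* **Model fitting** per trial in the frequency domain: Nelder-Mead over the
  log10 parameters matching the empirical transfer function (perturbation
  to input) and the control-input power spectrum.
* **Analyses:** implied-vs-observed RMS error, the effort/performance
  Pareto front traced by `rho` under signal-dependent noise, the
  noise-increase experiment ("slower response, unchanged latency"), Hankel
  singular value controller complexity, and Welch group statistics.

## Worked example

```python
import numpy as np
import visuotrack as vt

constants = vt.TaskConstants()
params = vt.SubjectParameters(
    latency_tau=0.26, noise_intensity=1.8e-3,
    noise_bandwidth=8.9, rho=0.19,
)

# simulate a session and fit trial 3
d_list = vt.generate_perturbations(constants, 4, seed=42)
trial = vt.simulate_subject(constants, params, d_list, seed=7)[2]
fit = vt.fit_trial(trial, constants)
print(fit.params.latency_tau, fit.implied_rms_e / fit.observed_rms_e)
```

Running `python examples/03_fit_model_to_trial.py` (this computation)
prints:

```
            truth     fitted
latency [s]          0.2600    0.2544
intensity            0.0018    0.0021
bandwidth [rad/s]    8.9000    7.5414
rho                  0.1900    0.3241

fit cost J = 152.60 (weighted frequency-domain discrepancy)
implied / observed RMS error = 1.086 (near 1.0 means the fitted model accounts for the tracking error)
```

The fitted latency lands within ~10 ms of the generating value; the noise
and effort parameters show typical single-trial scatter (a tenth to a
quarter of a log10 decade — averaging a subject's eight analyzed trials
reduces this severalfold), and the fitted model accounts for the observed
tracking error (ratio near 1).  The other examples show latency estimation
(`02`), the slowing-without-latency-change experiment (`04`), and the full
pipeline with group statistics (`05`).

## Layout

```
src/visuotrack/
  statespace.py   linear-systems substrate (interconnection, Pade delay,
                  Riccati/Lyapunov, balancing/HSVs, ZOH simulation)
  plant.py        9-state augmented plant + LQG synthesis + predictions
  cohort.py       protocol simulation and synthetic cohort generation
  latency.py      whitening, cross-correlation, onset estimation
  fitting.py      spectral estimation, per-trial model fits, Pareto front
  complexity.py   controller HSVs, derived noise measure, Welch tests
  pipeline.py     end-to-end orchestration and report bundle
docs/methods.md   model, estimators, numerical choices, limitations
examples/         one short narrative script per capability
```
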