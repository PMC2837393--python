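# Methods

## The task and its model

In compensatory tracking, a subject moves a manipulandum to keep a displayed
cursor at the center of a screen while software adds a random perturbation to
the cursor's velocity.  The cursor obeys

    de/dt = u(t) + d(t)

where `e` is the displayed error (in units of the screen half-width), `u` the
subject's control input, and `d` a band-limited Gaussian perturbation
produced by passing discrete white noise through a first-order low-pass
filter.  These marginally unstable dynamics are calibrated so that an
uncorrected cursor drifts off the screen in roughly ten seconds.

The subject is modeled as the LQG-optimal controller for a 9-state
continuous-time plant:

| states | subsystem |
|---|---|
| 1 | cursor error `e` (pure integrator) |
| 1 | perturbation prefilter (first-order low-pass, unit DC gain) |
| 2 | endogenous-noise prefilter (critically damped second order, unit DC gain) |
| 4 | fourth-order diagonal Pade approximation of the visuomotor latency on the measurement path |
| 1 | band-limited differentiator `a s/(s+a)` realizing the effort signal |

The subject minimizes `E[rho * (d/dt u_ideal)^2 + e^2]`.  The resulting
controller is a Kalman filter driven by the delayed error measurement plus a
static LQR gain on the state estimate: `xhat' = (A - B K - L C) xhat + L y`,
`u_ideal = -K xhat`.  The effort channel has a direct feedthrough of
`u_ideal`, so the LQR Riccati equation carries a state/input cross term; both
Riccati equations are solved with residual checks, and the closed loop's
eigenvalues are certified to split into regulator and estimator spectra (the
separation principle) to 1e-6 relative.

Four free parameters describe a subject:

| parameter | units | meaning | young / elderly group mean (log10) |
|---|---|---|---|
| `latency_tau` | s | lumped visuomotor latency | -0.5879 / -0.6252 |
| `noise_intensity` | units^2 s | variance per unit bandwidth of the white endogenous-noise source | -2.7556 / -2.6408 |
| `noise_bandwidth` | rad/s | corner of the endogenous-noise prefilter | 0.9495 / 0.9039 |
| `rho` | - | control cost plus multiplicative-noise coefficient (not separable under time-invariant control) | -0.7257 / -0.3010 |

Noise intensities are two-sided spectral densities with the convention
`var = (1/2pi) * integral S(omega) domega`; a white source of intensity `q`
sampled at `fs` has per-step variance `q*fs`.

## Task constants

| constant | default | rationale |
|---|---|---|
| sample rate | 100 Hz | protocol |
| trial length / warm-up discard | 60 s / 9 s | protocol (5100 analyzed samples) |
| perturbation prefilter corner | 0.3 Hz | the original corner is not recoverable from the source text; 0.3 Hz keeps the perturbation trackable but not trivially slow |
| perturbation white intensity | 0.106 | calibrated by bisection so the median first-passage time of the uncorrected cursor across the screen edge is 10 +- 1 s over 200 simulated trials (`calibrate_pert_intensity`) |
| differentiator corner | 100 rad/s | well above the closed-loop band (~10 rad/s), below Nyquist (314 rad/s) |
| measurement-noise variance | 1e-6 | measurement noise is physically negligible; a small positive value keeps the Kalman Riccati equation well posed.  This conditioning constant also controls how many controller states are dynamically significant; see "Known limitations". |

## Synthetic cohorts

Because no human recordings are distributed, every analysis stage is
validated on synthetic cohorts.  Subject parameters are drawn independently
per subject from log10-normal distributions with the group means above and
the aggregate SD column (0.1109, 0.5756, 0.2713, 0.4552) as between-subject
SDs.  All subjects of a session receive the same perturbation sequences in
the same order; the first two trials are treated as practice and excluded
from analysis.

The simulated world deliberately differs from the design model in two ways:

* the latency is a true integer-sample delay of the displayed error, while
  the subject's internal model uses the Pade approximation — fitting must
  therefore be robust to the Pade mismatch;
* the endogenous noise is a per-step white Gaussian sequence (variance
  `intensity * sample_rate`) through the ZOH-discretized noise filter rather
  than an exact continuous-time process.

The discrete world has a one-sample (10 ms) pipeline delay — a perturbation
sample first affects the displayed error at the next software update — so the
generator's effective latency is `tau + dt`.  The controller is discretized
by the bilinear (Tustin) transform so that it responds to the current
displayed error without an additional hold delay, as the continuous
controller does.  What passing tests on these cohorts do **not** show:
robustness to learning trends, control deadbands/intermittent stillness,
non-Gaussian or nonstationary noise, or measurement dropout, none of which
the generator emulates.

## Cross-correlation latency

The perturbation is whitened by exactly inverting the discrete generating
filter (`w_k = (d_{k+1} - a_d d_k)/b_d`, aligned so that lag zero means
"simultaneous with the perturbation's arrival in `d`"), then cross-correlated
with `u` (correlation-coefficient normalization), de-biased by the mean over
acausal lags, and smoothed with a zero-phase second-order 20 Hz Butterworth
filter.  The corrective response appears as a negative excursion; its onset
is the latency.

Locating the onset on the second derivative needs care: the excursion has a
soft corner (the Kalman innovation at onset is small because the internal
model pre-responds), so the curvature is step-like — it rises at the onset
and stays elevated through the rise.  The literal curvature argmax therefore
drifts ~30-70 ms into the rise.  The estimator instead takes the first lag at
which the second central difference (5-sample half-stencil, which suppresses
differencing noise) reaches 80% of its pre-trough maximum, with a floor of
three acausal-lag curvature SDs, searched in a 0.05-0.60 s window and capped
at the trough.  A trial with no excursion below three acausal-lag SDs raises
a "no response detected" error.  On synthetic calibration runs (true delays
150-350 ms, typical noise) the estimator's mean error is within 25 ms with
slope 0.87-0.95.  `subject_latency` averages the unsmoothed correlations over
a subject's trials before locating the onset, which keeps detection reliable
at noise levels where single trials fall below threshold.

## Frequency-domain fitting

Per analyzed trial, `estimate_spectra` computes the empirical transfer
estimate `H_hat = smooth(S_du)/smooth(S_dd)` (Daniell smoothing over 11
Fourier bins) and the raw periodogram of `u`.  Two numerical choices matter:

* **Hann taper.** The control-input spectrum spans four decades; the
  rectangular window's sidelobes leak low-frequency power into the
  high-frequency bins, raising the apparent noise floor there by an order of
  magnitude and corrupting the noise-parameter fit.  All spectra are
  estimated with a Hann taper (`taper=None` restores the plain periodogram,
  for which Parseval holds exactly).
* **Matched smoothing.** Smoothing a complex spectrum whose phase rotates
  across the smoothing span shrinks its magnitude.  The model prediction is
  therefore passed through the identical smoothing
  (`smooth(H_model * S_dd)/smooth(S_dd)`) before being compared with
  `H_hat`, so the smoothing bias cancels instead of biasing the parameters.

The fit minimizes, over the four log10 parameters (Nelder-Mead, box bounds
tau in [0.1, 1] s, bandwidth in [1, 100] rad/s, intensity and rho in
[1e-5, 1e2]),

    J = sum_k W_k |H_hat_k - H_k(theta)|^2  +  lam * spectrum_term

with `W(omega) = omega^2 / (1 + (omega/6)^4)`, zero above 30 rad/s
(emphasizing the band near the closed-loop bandwidth, where latency and
noise parameters are informative), and `lam = 1`.  The spectrum term is the
Whittle deviance `s_hat/s - log(s_hat/s) - 1`, which is minimized in
expectation at the true spectrum for chi-squared periodogram bins across the
spectrum's whole dynamic range (an absolute quadratic would be dominated by
the few largest low-frequency bins).  The model transfer is evaluated with a
half-sample delay factor `exp(-i omega dt/2)` accounting for the sampled
world's discrete integration.

The fit runs in two stages.  Stage 1 searches all four parameters with the
spectrum term comparing the raw periodogram of `u` against the model's
total spectrum; this identifies latency and `rho` well, but when the noise
corner lies below ~4 rad/s — where the total spectrum is dominated by the
deterministic response to the known perturbation — the noise intensity can
wander by a decade along an intensity/bandwidth valley.  Stage 2 therefore
refits intensity and bandwidth alone, holding latency and `rho` fixed,
against the *residual* periodogram `|U - H_hat D|^2` (the power of `u` not
explained by the empirical response to the perturbation).  The model-side
expectation of that residual is

    S_noise * (1 + 1/K)  +  |H - E[H_hat]|^2 * S_dd

with `K = 11` smoothing bins and `E[H_hat]` the model transfer passed
through the Daniell smoothing: the second term is the smoothing bias of the
empirical transfer leaking response power into the residual (dominant below
~2 rad/s, where the loop transfer curves within the smoothing span).
Accounting for that leakage is what makes the residual comparison unbiased;
without it, quiet subjects' noise intensity is overestimated several-fold.

The latency coordinate additionally carries a weak quadratic prior pulling
`log10 tau` toward the trial's cross-correlation estimate (weight 20 per
squared decade, versus a data curvature of roughly 600 per squared decade
for a typical subject, with a population-typical 0.25 s anchor when no
onset is detected).  For weak responders — high `rho`, the sluggish end of
the elderly range — the frequency-domain cost has a shallow valley trading
post-onset sluggishness against delay, and per-trial latency fits can
drift upward by 0.2-0.4 decades; the prior tie-breaks that valley toward
the model-free estimate while leaving well-identified fits essentially
untouched.  A consequence worth keeping in mind is that the agreement
between model-based and cross-correlation latencies is partly built in by
this regularization (the fit starts are centered on the cross-correlation
estimate in any case).

Synthesis failures inside the simplex return a large finite penalty so the
search can retreat.  Stage-1 starts are ranked by cost over a coarse grid
with the latency coordinate seeded by the cross-correlation estimate; one
start suffices in practice (the optimizer converges in ~200 evaluations,
well under the 350-evaluation cap, and additional restarts were never
observed to improve the optimum), and `FitConfig(n_restarts=...)` controls
it.  On a synthetic development cohort (24 subjects, 4 analyzed trials
each) the per-subject mean fits recover the generating parameters with
median absolute log10 errors of 0.018 (latency), 0.11 (intensity), 0.014
(bandwidth) and 0.10 (rho), with truth-fit correlations of 0.95-0.99.

## Implied RMS error, Pareto front, complexity

* `implied_rms_error` combines the deterministic closed-loop response to the
  recorded perturbation (zero initial conditions, warm-up discarded) with
  the stationary endogenous-noise variance from a Lyapunov equation, as a
  root sum of squares.
* `pareto_front` traces the effort/performance tradeoff by varying `rho`
  and coupling the noise intensity to the stationary mean square of `du/dt`
  (signal-dependent noise): `intensity = coeff * MS(udot)`, solved by fixed
  point with a bracketed root solve as fallback where the iteration loses
  contraction (small `rho`).  The coupling coefficient for a cohort is
  obtained by `fit_front_coefficient`, a least-squares fit of the traced
  curve to the cohort's observed (rms udot, rms e) cloud — fitting the
  tradeoff line to the young data rather than bounding it.  At strong
  coupling the low-`rho` head of the trace is dominated (extra effort feeds
  back enough noise to raise the error); `efficient_front` trims to the
  non-dominated tail, which is the frontier proper.
* `controller_hsvs` computes Hankel singular values of the controller as a
  standalone stable system (input: the measurement; output: the ideal
  control), via Lyapunov Gramians and an eigen-factorization balancing with
  values below `1e-12 * sigma_1` floored to zero.  Normalization divides by
  the subject's mean first HSV, so gain differences are not read as
  complexity.  Unstable fitted controllers (possible at extreme parameters)
  are excluded from HSV statistics.
* Group comparisons are Welch two-tailed t-tests on exactly one value per
  subject (per-subject means); pooled-trial testing is structurally
  impossible in the API.

## Problem sizes

The full synthetic experiment uses 12 young + 12 elderly subjects, ten 60-s
trials each with trials 3-10 analyzed (192 per-trial fits), a 15-point
`rho` grid for the Pareto front, and 8 analyzed trials per subject for
latency statistics.  The noise-increase experiment re-designs and
re-simulates each fitted young model at 4x noise intensity.

## Known limitations

* The perturbation-filter corner and the plant/screen scaling of the
  original experiment are not recoverable; synthetic defaults adopt a unit
  screen half-width, so noise intensities are comparable only internally.
* The measurement-noise conditioning constant trades off two published
  observations: at 1e-6 the HSV-versus-rho direction (higher rho gives
  smaller normalized 3rd/4th HSVs) holds, but the fifth HSV sits near 2% of
  the first rather than below 1%; raising the constant to 1e-5 reverses the
  3rd-HSV direction while pushing the fifth HSV below 1%.  The default keeps
  the mechanism (HSVs respond most strongly to `rho`) and accepts the larger
  fifth HSV.
* Latency recovery degrades for weak responders (high `rho` combined with
  high noise bandwidth), the same subjects for which the cross-correlation
  estimator may detect no response; the original study likewise excluded
  poorly fit subjects from some analyses.
* Raising the noise intensity lowers the closed-loop response magnitude
  through ~20 rad/s but *raises* it by 1-2% above ~24 rad/s, where the
  magnitude is below 0.04; "noise slows the response" is a mid-band
  statement.
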