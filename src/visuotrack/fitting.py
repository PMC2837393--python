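"""Frequency-domain estimation and four-parameter model fitting.

Each trial yields an empirical transfer-function estimate from perturbation
to control input (smoothed cross-spectrum over smoothed auto-spectrum) and a
raw periodogram of the control input.  The four subject parameters are
recovered per trial by Nelder-Mead minimization, in log10 parameter space,
of a frequency-weighted quadratic discrepancy between these estimates and
the closed-loop transfer/spectrum predicted by the LQG model.  The module
also traces the effort/performance Pareto front implied by the model when
the control-cost parameter is varied with signal-dependent noise coupling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
from scipy import optimize

from .cohort import TrialRecord
from .latency import trial_latency, NoResponseError
from .plant import (
    SubjectParameters,
    TaskConstants,
    assemble_plant,
    closed_loop,
    design_lqg,
    predicted_response,
    implied_rms_error,
    stationary_output_variance,
)
from .statespace import SynthesisError, frequency_response

#: log10 box bounds for [latency_tau (s), noise_intensity, noise_bandwidth
#: (rad/s), rho]; generous enough for both cohorts, tight enough that LQG
#: synthesis stays well-posed everywhere inside.
LOG10_BOUNDS = np.array(
    [
        [-1.0, 0.0],     # tau in [0.1, 1] s
        [-5.0, 2.0],     # intensity
        [0.0, 2.0],      # bandwidth in [1, 100] rad/s
        [-5.0, 2.0],     # rho
    ]
)

PENALTY = 1e6


@dataclass
class SpectralEstimate:
    """Empirical transfer estimate and control-input power spectrum.

    ``H_hat`` is the Daniell-smoothed cross- over auto-spectrum ratio; the
    raw cross/auto spectra are retained so a model prediction can be passed
    through the *same* smoothing when compared against ``H_hat`` (smoothing
    a rotating complex spectrum shrinks its magnitude, and a fair comparison
    must bias both sides identically).
    """

    omega: np.ndarray          # rad/s, ascending, DC excluded
    H_hat: np.ndarray          # complex, smoothed S_du / S_dd
    S_uu_hat: np.ndarray       # raw two-sided periodogram of u (units^2 s)
    S_dd_raw: np.ndarray       # raw periodogram of d
    S_du_raw: np.ndarray       # raw cross periodogram conj(D) U
    S_res: np.ndarray | None = None  # residual periodogram |U - H_hat D|^2
    n_samples: int = 0
    smoothing_halfwidth: int = 0

    def __post_init__(self):
        if np.any(self.S_uu_hat < 0):
            raise ValueError("power spectrum must be nonnegative")
        if self.omega.shape != self.H_hat.shape or self.omega.shape != self.S_uu_hat.shape:
            raise ValueError("omega, H_hat and S_uu_hat must share one grid")

    def smooth(self, x: np.ndarray) -> np.ndarray:
        """Daniell smoothing (reflected edges) on this estimate's grid."""
        M = self.smoothing_halfwidth
        kernel = np.ones(2 * M + 1) / (2 * M + 1)
        xp = np.concatenate([x[M:0:-1], x, x[-2:-M - 2:-1]])
        return np.convolve(xp, kernel, mode="valid")

    def to_csv(self, path) -> None:
        """Write the estimate as CSV (omega, Re H, Im H, S_uu)."""
        header = "omega_rad_s,re_H,im_H,S_uu"
        rows = "\n".join(
            f"{w:.6g},{h.real:.9g},{h.imag:.9g},{s:.9g}"
            for w, h, s in zip(self.omega, self.H_hat, self.S_uu_hat)
        )
        with open(path, "w") as fh:
            fh.write(header + "\n" + rows + "\n")

    def smoothed_transfer(self, h_model: np.ndarray) -> np.ndarray:
        """Model transfer smoothed exactly as the empirical estimate.

        smooth(H_model * S_dd) / smooth(S_dd): at the true parameters this
        has the same smoothing bias as H_hat, so their difference is noise.
        """
        return self.smooth(h_model * self.S_dd_raw) / self.smooth(self.S_dd_raw)


@dataclass
class FitResult:
    """Per-trial fit of the four-parameter LQG model."""

    params: SubjectParameters
    log10_params: np.ndarray
    cost: float
    converged: bool
    n_restarts_used: int
    implied_rms_e: float
    observed_rms_e: float
    subject_id: str = ""
    trial_index: int = 0


def estimate_spectra(
    trial: TrialRecord,
    constants: TaskConstants,
    smoothing_halfwidth: int = 5,
    max_omega: float | None = None,
    taper: str | None = "hann",
) -> SpectralEstimate:
    """Empirical Ĥ(ω) = S̄_du/S̄_dd and raw periodogram of u.

    Cross- and auto-spectra are Daniell-smoothed (boxcar over ``2M+1``
    Fourier bins, M = ``smoothing_halfwidth``); the power spectrum of u is
    deliberately left unsmoothed.  Spectra are two-sided densities: the
    variance of a series equals the integral of its periodogram over omega
    divided by 2*pi.

    A Hann data taper is applied by default.  The control-input spectrum
    spans four decades, and the rectangular window's sidelobes leak enough
    low-frequency power into the high-frequency bins to raise the apparent
    noise floor there by an order of magnitude; the taper removes that bias
    (``taper=None`` recovers the plain periodogram, for which the Parseval
    identity holds exactly).
    """
    n = trial.n_samples
    M = smoothing_halfwidth
    if n < 20 * (2 * M + 1):
        raise ValueError("trial too short for the requested smoothing span")
    fs = trial.sample_rate
    dt = 1.0 / fs
    d = trial.d - trial.d.mean()
    u = trial.u - trial.u.mean()
    if taper is None:
        w = np.ones(n)
    elif taper == "hann":
        w = np.hanning(n)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    norm = dt / np.sum(w ** 2)
    D = np.fft.rfft(d * w)
    U = np.fft.rfft(u * w)
    S_dd = (np.abs(D) ** 2) * norm
    S_du = (np.conj(D) * U) * norm
    S_uu = (np.abs(U) ** 2) * norm

    kernel = np.ones(2 * M + 1) / (2 * M + 1)
    # reflect at the edges so DC/Nyquist bins do not bias the ends
    def smooth(x):
        xp = np.concatenate([x[M:0:-1], x, x[-2:-M - 2:-1]])
        return np.convolve(xp, kernel, mode="valid")

    H_hat = smooth(S_du) / smooth(S_dd)
    # residual periodogram: the part of u's power not explained by the
    # (empirical) linear response to the known perturbation -- the
    # endogenous-noise spectrum estimate
    S_res = (np.abs(U - H_hat * D) ** 2) * norm
    omega = 2.0 * np.pi * np.fft.rfftfreq(n, d=dt)
    keep = omega > 0
    if max_omega is not None:
        keep &= omega <= max_omega
    return SpectralEstimate(
        omega=omega[keep],
        H_hat=H_hat[keep],
        S_uu_hat=S_uu[keep],
        S_dd_raw=S_dd[keep],
        S_du_raw=S_du[keep],
        S_res=S_res[keep],
        n_samples=n,
        smoothing_halfwidth=M,
    )


def band_weight(omega: np.ndarray, peak_omega: float = 6.0,
                cutoff: float = 30.0) -> np.ndarray:
    """Frequency weight emphasizing the closed-loop bandwidth region.

    W(omega) = omega^2 / (1 + (omega/peak_omega)^4), zeroed above ``cutoff``:
    rises through the low-frequency band (which carries little latency
    information), peaks near the closed-loop bandwidth and decays where
    coherence is lost; normalized to unit mean over its support.
    """
    w = omega ** 2 / (1.0 + (omega / peak_omega) ** 4)
    w = np.where(omega > cutoff, 0.0, w)
    s = w[w > 0]
    if s.size:
        w = w / s.mean()
    return w


def _model_spectra(
    theta_log10: np.ndarray,
    constants: TaskConstants,
    omega: np.ndarray,
    sampling_delay: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Model H_ud, total S_uu, and noise-only S at the data frequencies."""
    params = SubjectParameters.from_log10(theta_log10)
    plant = assemble_plant(constants, params)
    controller = design_lqg(plant)
    cl = closed_loop(plant, controller)
    if not cl.sys.is_stable():
        raise SynthesisError("closed loop unstable")
    fr = frequency_response(cl.sys, omega)
    iu = cl.output_index["u"]
    h = fr.values[:, iu, cl.input_index["d_ext"]]
    H_wu = fr.values[:, iu, cl.input_index["w"]]
    H_nu = fr.values[:, iu, cl.input_index["n_w"]]
    S_noise = np.abs(H_nu) ** 2 * params.noise_intensity
    S_total = (
        np.abs(H_wu) ** 2 * constants.pert_white_intensity + S_noise
    )
    if sampling_delay > 0:
        # the sampled world integrates the held perturbation over one step
        # before it is displayed; fold that known lag into the model phase
        h = h * np.exp(-1j * omega * sampling_delay)
    return h, S_total, S_noise


def fit_cost(
    theta_log10: np.ndarray,
    spectra: SpectralEstimate,
    constants: TaskConstants,
    weights: np.ndarray | None = None,
    lam: float = 1.0,
    sampling_delay: float | None = None,
    spectrum_mode: str = "combined",
    latency_prior: tuple[float, float] | None = None,
) -> float:
    """Weighted frequency-domain discrepancy J(theta).

    J = sum_k W_k |H_hat_k - H_k(theta)|^2
        + lam * sum_k W_k * dev(S_res_k, S_noise_k(theta))

    The transfer term compares the smoothed empirical estimate against the
    model prediction passed through the identical smoothing.  The
    power-spectrum term compares the *residual* periodogram of u (power not
    explained by the empirical linear response to the known perturbation)
    against the model's endogenous-noise spectrum: at low frequencies the
    total spectrum of u is dominated by the deterministic response to d,
    which would mask the noise parameters.  The discrepancy uses the
    Whittle deviance ``dev(shat, s) = shat/s - log(shat/s) - 1``, which is
    nonnegative, zero only at equality, and minimized in expectation at the
    true spectrum for periodogram (chi-squared) data across its whole
    dynamic range -- an absolute quadratic would be dominated entirely by
    the few largest low-frequency bins.  Synthesis failures and
    out-of-bounds parameters return a large finite penalty (plus distance
    from the box) so a simplex can retreat.
    """
    theta = np.asarray(theta_log10, dtype=float)
    over = np.maximum(theta - LOG10_BOUNDS[:, 1], 0.0)
    under = np.maximum(LOG10_BOUNDS[:, 0] - theta, 0.0)
    if np.any(over > 0) or np.any(under > 0):
        return PENALTY * (1.0 + float(np.sum(over + under)))
    omega = spectra.omega
    W = band_weight(omega) if weights is None else weights
    if sampling_delay is None:
        sampling_delay = 0.5 / constants.sample_rate
    try:
        h, S_total, S_noise = _model_spectra(theta, constants, omega,
                                             sampling_delay)
    except (SynthesisError, ValueError):
        return PENALTY
    h_cmp = spectra.smoothed_transfer(h)

    def deviance(s_emp, s_mod):
        s_mod = np.maximum(s_mod, 1e-300)
        ratio = np.maximum(s_emp, 1e-300) / s_mod
        return np.sum(W * (ratio - np.log(ratio) - 1.0))

    # the residual comparison isolates the endogenous-noise parameters that
    # the response-dominated total spectrum masks at low frequency
    if spectrum_mode == "total" or (
        spectrum_mode != "whittle" and spectra.S_res is None
    ):
        spec_term = deviance(spectra.S_uu_hat, S_total)
    elif spectrum_mode == "residual":
        # E|U - H_hat D|^2 = S_noise (1 + 1/K) + |H - E[H_hat]|^2 S_dd:
        # the second term is the Daniell smoothing bias of H_hat leaking
        # response power into the residual (dominant at low frequency where
        # the loop transfer curves within the smoothing span); both parts
        # are computable from the model side
        K = 2 * spectra.smoothing_halfwidth + 1
        S_res_model = (
            S_noise * (1.0 + 1.0 / K)
            + np.abs(h - h_cmp) ** 2 * spectra.S_dd_raw
        )
        spec_term = deviance(spectra.S_res, S_res_model)
    elif spectrum_mode == "combined":
        spec_term = 0.5 * (
            deviance(spectra.S_uu_hat, S_total)
            + deviance(spectra.S_res, S_noise)
        )
    elif spectrum_mode == "whittle":
        # exact per-bin residual against the *model* transfer:
        # |U - H(theta) D|^2 = S_uu - 2 Re(conj(H) S_du) + |H|^2 S_dd,
        # compared with the model noise spectrum -- the Whittle likelihood
        # of U given the known perturbation
        s_resid = (
            spectra.S_uu_hat
            - 2.0 * np.real(np.conj(h) * spectra.S_du_raw)
            + np.abs(h) ** 2 * spectra.S_dd_raw
        )
        spec_term = deviance(np.maximum(s_resid, 0.0), S_noise)
    else:
        raise ValueError(f"unknown spectrum_mode {spectrum_mode!r}")
    J = float(
        np.sum(W * np.abs(spectra.H_hat - h_cmp) ** 2) + lam * spec_term
    )
    if latency_prior is not None:
        # weak quadratic pull of log10(tau) toward the model-free estimate:
        # tie-breaks the latency/sluggishness valley of weak responders
        # without moving well-identified fits (their own curvature in tau is
        # an order of magnitude larger than the prior weight)
        mu, anchor = latency_prior
        J += mu * (theta[0] - anchor) ** 2
    return J if np.isfinite(J) else PENALTY


@dataclass
class FitConfig:
    """Knobs of the per-trial fitting procedure."""

    n_restarts: int = 2
    lam: float = 1.0
    max_omega: float = 35.0       # rad/s retained from the spectra
    xatol: float = 1e-4           # simplex size in log10 units
    fatol: float = 1e-9
    maxfev: int = 500
    min_trial_index: int = 3      # trials 1-2 carry learning effects
    spectrum_mode: str = "total"  # spectrum term of the stage-1 cost
    refine_noise: bool = True     # stage-2 noise fit on the residual spectrum
    latency_prior_weight: float = 20.0  # 0 disables the log10-tau prior


def _start_points(
    trial: TrialRecord,
    spectra: SpectralEstimate,
    constants: TaskConstants,
    config: FitConfig,
    tau0: float,
) -> list[np.ndarray]:
    """Multi-start initial simplex centers.

    The latency coordinate starts from the cross-correlation estimate; the
    other coordinates from a coarse grid over plausible noise/effort levels
    ranked by the fit cost.
    """
    lt = math.log10(np.clip(tau0, 0.11, 0.9))
    grid = [
        np.array([lt, li, lb, lr])
        for li in (-3.3, -2.7, -2.1)
        for lb in (0.95,)
        for lr in (-1.2, -0.6, 0.0)
    ]
    W = band_weight(spectra.omega)
    costs = [
        fit_cost(g, spectra, constants, weights=W, lam=config.lam) for g in grid
    ]
    order = np.argsort(costs)
    return [grid[i] for i in order[: config.n_restarts]]


def fit_trial(
    trial: TrialRecord,
    constants: TaskConstants,
    config: FitConfig | None = None,
) -> FitResult:
    """Fit the four-parameter model to one trial by Nelder-Mead.

    Stage 1 runs ``n_restarts`` Nelder-Mead minimizations over all four
    log10 parameters from ranked coarse-grid starts and keeps the best.
    Stage 2 (``refine_noise``) refits the two noise parameters alone against
    the residual spectrum -- the part of u's power not explained by the
    response to the known perturbation -- holding latency and rho fixed.
    The total spectrum identifies latency and rho well but lets the noise
    intensity wander by a decade when the noise corner hides below the
    response-dominated band; the residual comparison pins it without
    disturbing the other two parameters.  Also reports the model-implied
    and observed RMS error of the trial.
    """
    config = config or FitConfig()
    if trial.trial_index < config.min_trial_index:
        raise ValueError(
            f"trial {trial.trial_index} is a learning trial "
            f"(min_trial_index={config.min_trial_index}); pass a config to override"
        )
    spectra = estimate_spectra(trial, constants, max_omega=config.max_omega)
    W = band_weight(spectra.omega)
    try:
        tau0 = trial_latency(trial, constants)
    except (NoResponseError, ValueError):
        tau0 = 0.25  # population-typical fallback when no onset is detected
    prior = None
    if config.latency_prior_weight > 0:
        prior = (config.latency_prior_weight,
                 math.log10(np.clip(tau0, 0.11, 0.9)))
    args = (spectra, constants, W, config.lam, None, config.spectrum_mode,
            prior)

    best = None
    n_used = 0
    for x0 in _start_points(trial, spectra, constants, config, tau0):
        n_used += 1
        res = optimize.minimize(
            fit_cost,
            x0,
            args=args,
            method="Nelder-Mead",
            options=dict(
                xatol=config.xatol, fatol=config.fatol, maxfev=config.maxfev,
                initial_simplex=_initial_simplex(x0),
            ),
        )
        if best is None or res.fun < best.fun:
            best = res
    if best is None or best.fun >= PENALTY:
        raise SynthesisError("all fit restarts failed LQG synthesis")

    x = np.asarray(best.x, dtype=float)
    if config.refine_noise and spectra.S_res is not None:
        x = _refine_noise_parameters(x, spectra, constants, W, config)
        best_fun = fit_cost(x, *args)
    else:
        best_fun = float(best.fun)

    params = SubjectParameters.from_log10(x)
    plant = assemble_plant(constants, params)
    controller = design_lqg(plant)
    implied = implied_rms_error(plant, controller, trial.d, constants)
    observed = float(np.sqrt(np.mean(trial.e ** 2)))
    return FitResult(
        params=params,
        log10_params=x,
        cost=float(best_fun),
        converged=bool(best.success),
        n_restarts_used=n_used,
        implied_rms_e=implied,
        observed_rms_e=observed,
        subject_id=trial.subject_id,
        trial_index=trial.trial_index,
    )


def _refine_noise_parameters(
    x: np.ndarray,
    spectra: SpectralEstimate,
    constants: TaskConstants,
    W: np.ndarray,
    config: FitConfig,
) -> np.ndarray:
    """Stage-2 fit of (intensity, bandwidth) on the residual spectrum."""

    def cost(ib: np.ndarray) -> float:
        theta = np.array([x[0], ib[0], ib[1], x[3]])
        return fit_cost(theta, spectra, constants, weights=W,
                        lam=config.lam, spectrum_mode="residual")

    ib0 = x[1:3].copy()
    simplex = np.array([ib0, ib0 + [0.2, 0.0], ib0 + [0.0, 0.15]])
    res = optimize.minimize(
        cost, ib0, method="Nelder-Mead",
        options=dict(xatol=max(config.xatol, 1e-3), fatol=config.fatol,
                     maxfev=120, initial_simplex=simplex),
    )
    if res.fun >= PENALTY:
        return x
    out = x.copy()
    out[1:3] = res.x
    return out


def _initial_simplex(x0: np.ndarray) -> np.ndarray:
    """Simplex spanning the local parameter scale (0.15 log10 units)."""
    n = x0.size
    simplex = np.tile(x0, (n + 1, 1))
    for i in range(n):
        simplex[i + 1, i] += 0.15 if x0[i] < LOG10_BOUNDS[i, 1] - 0.2 else -0.15
    return simplex


def fir_reference_cost(
    spectra: SpectralEstimate,
    constants: TaskConstants,
    n_taps: int = 40,
    lam: float = 1.0,
) -> float:
    """Fit cost achieved by an unconstrained delayed-FIR transfer fit.

    A generic linear model (FIR filter on the perturbation, least squares in
    the weighted frequency domain, with the power spectrum matched exactly at
    the optimum of its term) gives a floor for the transfer-discrepancy part
    of the cost that no controller-structure restriction can beat.  Used as
    an independent near-optimality reference for the LQG-constrained fit.
    """
    omega = spectra.omega
    W = band_weight(omega)
    dt = 1.0 / constants.sample_rate
    # design matrix: H_fir(w) = sum_k c_k exp(-i w k dt)
    E = np.exp(-1j * np.outer(omega, np.arange(n_taps) * dt))
    sw = np.sqrt(W)
    A = E * sw[:, None]
    b = spectra.H_hat * sw
    A_ri = np.vstack([A.real, A.imag])
    b_ri = np.concatenate([b.real, b.imag])
    c, *_ = np.linalg.lstsq(A_ri, b_ri, rcond=None)
    resid = b - A @ c
    # the free model can match S_uu_hat exactly, so its term contributes 0
    return float(np.sum(np.abs(resid) ** 2))


def pareto_front(
    constants: TaskConstants,
    mult_noise_coeff: float,
    rho_grid: np.ndarray,
    latency_tau: float = 10 ** -0.5879,
    noise_bandwidth: float = 10 ** 0.9495,
    tol: float = 1e-4,
    max_iter: int = 50,
) -> list[tuple[float, float]]:
    """Effort/performance tradeoff traced by the control-cost parameter.

    For each rho, iterate to the signal-dependent-noise fixed point: design
    the LQG controller, compute the stationary mean-square control-input
    velocity, set the endogenous-noise intensity to ``mult_noise_coeff *
    MS(udot)``, and repeat until the intensity is stationary.  Returns
    (rms_udot, rms_e) pairs, one per rho (ascending).
    """
    if mult_noise_coeff < 0:
        raise ValueError("mult_noise_coeff must be nonnegative")
    rho_grid = np.asarray(rho_grid, dtype=float)
    if np.any(np.diff(rho_grid) <= 0):
        raise ValueError("rho_grid must be ascending")
    def moments_at(rho: float, intensity: float) -> tuple[float, float]:
        params = SubjectParameters(
            latency_tau=latency_tau,
            noise_intensity=intensity,
            noise_bandwidth=noise_bandwidth,
            rho=rho,
        )
        plant = assemble_plant(constants, params)
        ctrl = design_lqg(plant)
        return closed_loop_moments(plant, ctrl, constants, params)

    out = []
    for rho in rho_grid:
        # fixed point of  intensity = coeff * MS(udot; intensity):
        # plain iteration first (fast when contractive), bracketed root
        # solve as fallback (the map loses contraction at small rho)
        intensity = 0.0
        converged = False
        for _ in range(max_iter):
            try:
                ms_udot, ms_e = moments_at(rho, intensity)
            except (SynthesisError, ValueError):
                intensity = max(intensity / 4.0, 1e-9)  # overshoot: fall back
                break
            if ms_udot <= 0:  # numerically degenerate Lyapunov solution
                intensity = max(intensity / 4.0, 1e-9)
                break
            new_int = mult_noise_coeff * ms_udot
            if abs(new_int - intensity) <= tol * max(intensity, 1e-12):
                intensity = new_int
                converged = True
                break
            intensity = new_int
        if not converged and mult_noise_coeff > 0:
            from scipy.optimize import brentq

            def gap(x: float) -> float:
                try:
                    return mult_noise_coeff * moments_at(rho, x)[0] - x
                except (SynthesisError, ValueError):
                    # synthesis breaks only at extreme intensities, far above
                    # the fixed point: steer the bracket back down
                    return -x

            hi = max(intensity, 1e-6)
            for _ in range(60):
                if gap(hi) < 0:
                    break
                hi *= 2.0
            else:
                raise RuntimeError(
                    f"signal-dependent-noise fixed point unbounded (rho={rho})"
                )
            intensity = brentq(gap, 0.0, hi, xtol=tol * max(hi, 1e-9))
            ms_udot, ms_e = moments_at(rho, intensity)
        elif not converged:
            raise RuntimeError(
                f"signal-dependent-noise fixed point did not converge (rho={rho})"
            )
        if not (ms_udot > 0 and ms_e > 0 and np.isfinite(ms_udot)
                and np.isfinite(ms_e)):
            raise RuntimeError(
                f"degenerate stationary moments at rho={rho} "
                f"(coefficient too large for a stable fixed point)"
            )
        out.append((math.sqrt(ms_udot), math.sqrt(ms_e)))
    return out


def efficient_front(
    points: list[tuple[float, float]]
) -> list[tuple[float, float]]:
    """Pareto-efficient subset of a traced (rms_udot, rms_e) curve.

    At strong signal-dependent-noise coupling the low-rho end of the traced
    curve turns back on itself (extra effort feeds enough extra noise that
    the error rises again); those points are dominated and are not part of
    the effort/performance frontier.  Returns the non-dominated points
    sorted by ascending effort.
    """
    pts = sorted(points)  # ascending effort
    out = []
    for ud, e in pts:
        if not out or e < out[-1][1]:
            out.append((ud, e))
    return out


def fit_front_coefficient(
    points: list[tuple[float, float]],
    constants: TaskConstants,
    rho_grid: np.ndarray,
    latency_tau: float = 10 ** -0.5879,
    noise_bandwidth: float = 10 ** 0.9495,
    bracket_log10: tuple[float, float] = (-4.0, -1.0),
) -> float:
    """Signal-dependent-noise coefficient that best fits a cohort's cloud.

    Fits the effort/performance front to observed (rms_udot, rms_e) points
    by least squares on log rms_e, searching the coupling coefficient on a
    log10 bracket.  This mirrors fitting the tradeoff line to the young
    subjects' data: the returned coefficient makes the traced front thread
    the cloud rather than bound it.
    """
    from scipy.optimize import minimize_scalar

    ud_obs = np.array([p[0] for p in points])
    e_obs = np.array([p[1] for p in points])

    def misfit(log_coeff: float) -> float:
        try:
            front = pareto_front(
                constants, 10.0 ** log_coeff, rho_grid,
                latency_tau=latency_tau, noise_bandwidth=noise_bandwidth,
            )
        except RuntimeError:
            return 1e6
        fu = np.array([f[0] for f in front])
        fe = np.array([f[1] for f in front])
        order = np.argsort(fu)
        pred = np.interp(ud_obs, fu[order], fe[order])
        return float(np.sum((np.log(e_obs) - np.log(pred)) ** 2))

    res = minimize_scalar(misfit, bounds=bracket_log10, method="bounded",
                          options=dict(xatol=0.02))
    return float(10.0 ** res.x)


def closed_loop_moments(plant, ctrl, constants, params) -> tuple[float, float]:
    """Stationary mean-square (udot, e) of the closed loop under both sources.

    The control-input velocity is that of the physical u = u_ideal + n:
    udot = -K (A_c xhat + L y) + x_n2, an exact linear function of the
    closed-loop state (no white feedthrough), so its stationary variance
    follows from the closed-loop Lyapunov equation.
    """
    from .statespace import solve_lyapunov

    cl = closed_loop(plant, ctrl)
    n_p = plant.sys.n_states
    K, L = ctrl.lqr_gain, ctrl.kalman_gain
    Cy = plant.sys.C[[plant.output_index["y"]], :]
    C_udot = np.zeros((1, cl.sys.n_states))
    C_udot[:, n_p:] = -K @ ctrl.sys.A
    C_udot[:, :n_p] = -(K @ L) @ Cy
    C_udot[0, plant.state_index["noise_f2"]] += 1.0
    C_e = np.zeros((1, cl.sys.n_states))
    C_e[0, plant.state_index["cursor_e"]] = 1.0

    cols = [cl.input_index["w"], cl.input_index["n_w"]]
    Bn = cl.sys.B[:, cols] * np.sqrt(
        [constants.pert_white_intensity, params.noise_intensity]
    )
    P = solve_lyapunov(cl.sys.A, Bn @ Bn.T)
    C = np.vstack([C_udot, C_e])
    var = np.diag(C @ P @ C.T)
    return float(var[0]), float(var[1])
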