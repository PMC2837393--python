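"""Augmented plant assembly and LQG controller synthesis.

The compensatory-tracking task is modeled as a 9-state continuous-time
linear plant seen from the subject's point of view:

* 1 state  -- the cursor error ``e`` (a pure integrator of control + perturbation),
* 1 state  -- first-order low-pass prefilter shaping the external perturbation,
* 2 states -- critically damped second-order prefilter shaping endogenous noise,
* 4 states -- fourth-order Pade approximation of the visuomotor latency on the
  displayed error, and
* 1 state  -- a high-corner filter realizing differentiation of the control
  input for the effort term of the quadratic cost.

The subject is modeled as the LQG-optimal controller for this plant: a Kalman
filter driven by the delayed error measurement plus an LQR gain on the state
estimate, minimizing E[rho * udot_ideal^2 + e^2].  Four free parameters
describe a subject: latency tau, endogenous-noise intensity and bandwidth,
and the control-cost/multiplicative-noise weight rho.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import linalg

from .statespace import (
    StateSpaceModel,
    FrequencyResponse,
    DimensionError,
    SynthesisError,
    discretize_zoh,
    feedback_loop,
    frequency_response,
    pade_delay,
    simulate,
    solve_care,
    solve_lyapunov,
)

STATE_LABELS = [
    "cursor_e",
    "pert_filter",
    "noise_f1",
    "noise_f2",
    "delay1",
    "delay2",
    "delay3",
    "delay4",
    "diff",
]


@dataclass
class TaskConstants:
    """Protocol and software constants of the tracking task.

    The screen half-width defines the unit of cursor error; the white
    perturbation intensity is calibrated so that an uncorrected cursor
    drifts off screen in about ten seconds (see
    :func:`visuotrack.cohort.calibrate_pert_intensity`).
    """

    sample_rate: float = 100.0        # Hz
    trial_length: float = 60.0        # s
    warmup_discard: float = 9.0       # s
    pert_cutoff: float = 0.3          # Hz, perturbation prefilter corner
    # calibrated so an uncorrected cursor crosses the screen edge in ~10 s
    pert_white_intensity: float = 0.106  # variance per unit bandwidth of w
    screen_halfwidth: float = 1.0     # error units
    diff_corner: float = 100.0        # rad/s, differentiator corner
    meas_noise_variance: float = 1e-6  # variance of v

    def __post_init__(self):
        for name in (
            "sample_rate", "trial_length", "warmup_discard", "pert_cutoff",
            "pert_white_intensity", "screen_halfwidth", "diff_corner",
            "meas_noise_variance",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.warmup_discard >= self.trial_length:
            raise ValueError("warmup_discard must be shorter than the trial")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_rate

    @property
    def n_keep(self) -> int:
        """Samples retained per trial after the warm-up discard."""
        return round((self.trial_length - self.warmup_discard) * self.sample_rate)

    def to_json(self) -> str:
        return json.dumps(asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "TaskConstants":
        return cls(**json.loads(s))


@dataclass
class SubjectParameters:
    """The four fitted quantities describing one subject's control strategy."""

    latency_tau: float        # s
    noise_intensity: float    # variance per unit bandwidth of the white source
    noise_bandwidth: float    # rad/s
    rho: float                # control cost + multiplicative-noise weight

    def __post_init__(self):
        if self.latency_tau <= 0:
            raise ValueError("latency_tau must be positive")
        if self.noise_intensity < 0:
            raise ValueError("noise_intensity must be nonnegative")
        if self.noise_bandwidth <= 0:
            raise ValueError("noise_bandwidth must be positive")
        if self.rho <= 0:
            raise ValueError("rho must be positive")

    def to_log10(self) -> np.ndarray:
        """Vector [log10 tau, log10 intensity, log10 bandwidth, log10 rho]."""
        return np.array(
            [
                math.log10(self.latency_tau),
                math.log10(self.noise_intensity),
                math.log10(self.noise_bandwidth),
                math.log10(self.rho),
            ]
        )

    @classmethod
    def from_log10(cls, v) -> "SubjectParameters":
        v = np.asarray(v, dtype=float)
        return cls(10.0 ** v[0], 10.0 ** v[1], 10.0 ** v[2], 10.0 ** v[3])

    def replace(self, **kw) -> "SubjectParameters":
        d = asdict(self)
        d.update(kw)
        return SubjectParameters(**d)


PARAM_NAMES = ("latency_tau", "noise_intensity", "noise_bandwidth", "rho")


@dataclass
class AugmentedPlant:
    """The 9-state design plant with its port and state index maps."""

    sys: StateSpaceModel            # inputs [u_ideal, w, n_w]; see output_index
    constants: TaskConstants
    params: SubjectParameters
    input_index: dict = field(default_factory=dict)
    output_index: dict = field(default_factory=dict)
    state_index: dict = field(default_factory=dict)


@dataclass
class ControllerModel:
    """LQG controller: Kalman filter + LQR gain, realized as y -> u_ideal."""

    sys: StateSpaceModel
    kalman_gain: np.ndarray   # (9, 1)
    lqr_gain: np.ndarray      # (1, 9)
    design_params: SubjectParameters

    def to_json(self) -> str:
        return json.dumps(
            {
                "sys": json.loads(self.sys.to_json()),
                "kalman_gain": self.kalman_gain.tolist(),
                "lqr_gain": self.lqr_gain.tolist(),
                "design_params": asdict(self.design_params),
            }
        )


def build_perturbation_filter(constants: TaskConstants) -> StateSpaceModel:
    """First-order unit-DC-gain low-pass shaping the perturbation.

    Corner at ``2*pi*pert_cutoff`` rad/s: dx = -wc x + wc w, d = x.
    """
    wc = 2.0 * math.pi * constants.pert_cutoff
    return StateSpaceModel(
        [[-wc]], [[wc]], [[1.0]], [[0.0]], state_labels=["pert_filter"]
    )


def build_noise_filter(noise_bandwidth: float) -> StateSpaceModel:
    """Critically damped second-order unit-DC-gain filter, double pole at -a."""
    if noise_bandwidth <= 0:
        raise ValueError("noise_bandwidth must be positive")
    a = float(noise_bandwidth)
    A = [[0.0, 1.0], [-a * a, -2.0 * a]]
    B = [[0.0], [a * a]]
    return StateSpaceModel(A, B, [[1.0, 0.0]], [[0.0]],
                           state_labels=["noise_f1", "noise_f2"])


def build_diff_filter(diff_corner: float) -> StateSpaceModel:
    """Bandlimited differentiator a*s/(s+a): dx = -a x + u, y = a u - a^2 x.

    For frequencies well below the corner ``a`` the gain is ~omega, which is
    what the effort term of the cost needs; the finite corner keeps the cost
    output proper so LQG synthesis stays well-posed.
    """
    if diff_corner <= 0:
        raise ValueError("diff_corner must be positive")
    a = float(diff_corner)
    if a < 50.0:
        import warnings

        warnings.warn(
            "diff_corner below 50 rad/s may distort the effort cost in the "
            "closed-loop band",
            stacklevel=2,
        )
    return StateSpaceModel([[-a]], [[1.0]], [[-a * a]], [[a]],
                           state_labels=["diff"])


def assemble_plant(
    constants: TaskConstants, params: SubjectParameters
) -> AugmentedPlant:
    """Assemble the 9-state augmented plant.

    Inputs: ``u_ideal`` (subject's noise-free control), ``w`` (white source of
    the perturbation), ``n_w`` (white source of endogenous noise).
    Outputs: ``y`` (delayed error measurement, noise added at design time),
    ``z1 = sqrt(rho) * d/dt u_ideal``, ``z2 = e`` (the cost channels),
    ``e`` and ``u = u_ideal + n`` (physical signals).
    """
    F = build_perturbation_filter(constants)
    N = build_noise_filter(params.noise_bandwidth)
    Dly = pade_delay(params.latency_tau, order=4)
    Dif = build_diff_filter(constants.diff_corner)
    sr = math.sqrt(params.rho)

    n = 9
    A = np.zeros((n, n))
    # state ordering per STATE_LABELS: e, xF, xn1, xn2, xd1..4, xu
    iE, iF, iN1, iN2, iD0, iU = 0, 1, 2, 3, 4, 8
    # cursor: de/dt = u_ideal + n + d
    A[iE, iF] = 1.0          # d = xF
    A[iE, iN1] = 1.0         # n = xn1
    A[iF, iF] = F.A[0, 0]
    A[iN1:iN2 + 1, iN1:iN2 + 1] = N.A
    A[iD0:iD0 + 4, iD0:iD0 + 4] = Dly.A
    A[iD0:iD0 + 4, iE] = Dly.B[:, 0]    # delay driven by e
    A[iU, iU] = Dif.A[0, 0]

    B = np.zeros((n, 3))   # [u_ideal, w, n_w]
    B[iE, 0] = 1.0
    B[iU, 0] = Dif.B[0, 0]
    B[iF, 1] = F.B[0, 0]
    B[iN1:iN2 + 1, 2] = N.B[:, 0]

    C = np.zeros((4, n))
    D = np.zeros((4, 3))
    # y = delayed e (Pade output includes a feedthrough of e)
    C[0, iD0:iD0 + 4] = Dly.C[0]
    C[0, iE] = Dly.D[0, 0]
    # z1 = sqrt(rho) * d/dt u_ideal
    C[1, iU] = sr * Dif.C[0, 0]
    D[1, 0] = sr * Dif.D[0, 0]
    # z2 = e
    C[2, iE] = 1.0
    # physical u = u_ideal + n
    C[3, iN1] = 1.0
    D[3, 0] = 1.0

    sys = StateSpaceModel(A, B, C, D, state_labels=list(STATE_LABELS))
    return AugmentedPlant(
        sys=sys,
        constants=constants,
        params=params,
        input_index={"u_ideal": 0, "w": 1, "n_w": 2},
        output_index={"y": 0, "z_udot": 1, "z_e": 2, "u": 3},
        state_index={lbl: i for i, lbl in enumerate(STATE_LABELS)},
    )


def design_lqg(
    plant: AugmentedPlant,
    constants: TaskConstants | None = None,
    params: SubjectParameters | None = None,
) -> ControllerModel:
    """Synthesize the LQG controller for an augmented plant.

    The LQR gain K minimizes E[rho*udot^2 + e^2] (cost channels z of the
    plant, including the feedthrough of u_ideal into the effort channel, which
    introduces a state/input cross term in the Riccati equation).  The Kalman
    gain L is designed for the white sources w, n_w and measurement noise v.
    The controller realization is xhat' = (A - B K - L C) xhat + L y,
    u_ideal = -K xhat.
    """
    constants = constants or plant.constants
    params = params or plant.params
    if constants.meas_noise_variance <= 0:
        raise SynthesisError("measurement noise variance must be positive")

    sys = plant.sys
    A = sys.A
    Bu = sys.B[:, [sys_in := plant.input_index["u_ideal"]]]
    Cz = sys.C[[plant.output_index["z_udot"], plant.output_index["z_e"]], :]
    Dz = sys.D[[plant.output_index["z_udot"], plant.output_index["z_e"]], :][:, [sys_in]]
    Cy = sys.C[[plant.output_index["y"]], :]

    Q = Cz.T @ Cz
    R = Dz.T @ Dz
    S = Cz.T @ Dz
    try:
        P = solve_care(A, Bu, Q, R, S=S)
    except SynthesisError as exc:
        raise SynthesisError(f"LQR synthesis failed: {exc}") from exc
    K = linalg.solve(R, (P @ Bu + S).T)

    G = sys.B[:, [plant.input_index["w"], plant.input_index["n_w"]]]
    Qw = np.diag([constants.pert_white_intensity, params.noise_intensity])
    Rv = np.array([[constants.meas_noise_variance]])
    try:
        Pf = solve_care(A.T, Cy.T, G @ Qw @ G.T, Rv)
    except SynthesisError as exc:
        raise SynthesisError(f"Kalman synthesis failed: {exc}") from exc
    L = Pf @ Cy.T / Rv[0, 0]

    Ac = A - Bu @ K - L @ Cy
    ctrl = StateSpaceModel(
        Ac, L, -K, np.zeros((1, 1)),
        state_labels=[f"xhat_{lbl}" for lbl in STATE_LABELS],
    )
    # separation: closed-loop spectrum = eig(A - Bu K) union eig(A - L Cy),
    # both certified Hurwitz by the stabilizing Riccati solutions above
    return ControllerModel(
        sys=ctrl, kalman_gain=L, lqr_gain=K, design_params=params
    )


@dataclass
class ClosedLoop:
    """Closed loop from [u_ext, w, n_w, d_ext] to [y, z1, z2, u, e]."""

    sys: StateSpaceModel
    input_index: dict
    output_index: dict


def closed_loop(plant: AugmentedPlant, controller: ControllerModel) -> ClosedLoop:
    """Connect the controller (input y, output u_ideal) around the plant.

    A direct perturbation-injection input ``d_ext`` (entering the cursor
    integrator alongside the prefilter output) and an explicit error output
    ``e`` are appended before closing the loop, so the closed loop exposes the
    transfer from the perturbation itself -- not its white source -- to the
    subject's response, as well as the noise-source channels.
    """
    sys = plant.sys
    iE = plant.state_index["cursor_e"]
    B = np.hstack([sys.B, np.zeros((sys.n_states, 1))])
    B[iE, -1] = 1.0  # d_ext enters like the filtered perturbation
    C = np.vstack([sys.C, np.zeros((1, sys.n_states))])
    C[-1, iE] = 1.0  # e
    D = np.pad(sys.D, ((0, 1), (0, 1)))
    open_sys = StateSpaceModel(B=B, A=sys.A, C=C, D=D,
                               state_labels=list(sys.state_labels))
    # controller output u_ideal adds at plant input 0; it reads output 0 (y);
    # the -K sign is internal to the controller, so the junction sign is +1
    cl = feedback_loop(open_sys, controller.sys, sign=+1)
    return ClosedLoop(
        sys=cl,
        input_index={"u_ext": 0, "w": 1, "n_w": 2, "d_ext": 3},
        output_index={"y": 0, "z_udot": 1, "z_e": 2, "u": 3, "e": 4},
    )


def predicted_response(
    plant: AugmentedPlant,
    controller: ControllerModel,
    omega_grid,
    constants: TaskConstants | None = None,
) -> tuple[FrequencyResponse, np.ndarray]:
    """Model-predicted closed-loop transfer H_ud and control spectrum S_uu.

    ``H_ud`` is the transfer from the (post-filter) perturbation d to the
    control input u.  ``S_uu`` is the two-sided power spectral density of u
    (units^2 * s, with variance = integral of S over omega / 2 pi) implied by
    both white sources driving the loop.
    """
    constants = constants or plant.constants
    cl = closed_loop(plant, controller)
    if not cl.sys.is_stable():
        raise SynthesisError("closed loop unstable: no stationary response")
    omega = np.asarray(omega_grid, dtype=float)
    fr = frequency_response(cl.sys, omega)
    iu = cl.output_index["u"]
    H_ud = FrequencyResponse(omega, fr.values[:, [iu], :][:, :, [cl.input_index["d_ext"]]])
    H_wu = fr.values[:, iu, cl.input_index["w"]]
    H_nu = fr.values[:, iu, cl.input_index["n_w"]]
    S_uu = (
        np.abs(H_wu) ** 2 * constants.pert_white_intensity
        + np.abs(H_nu) ** 2 * plant.params.noise_intensity
    )
    return H_ud, S_uu


def stationary_output_variance(
    cl: ClosedLoop, constants: TaskConstants, params: SubjectParameters,
    outputs: tuple[str, ...] = ("e",),
    sources: tuple[str, ...] = ("w", "n_w"),
) -> np.ndarray:
    """Stationary variances of closed-loop outputs under the white sources."""
    intensities = {"w": constants.pert_white_intensity,
                   "n_w": params.noise_intensity}
    cols = [cl.input_index[s] for s in sources]
    Bn = cl.sys.B[:, cols] * np.sqrt([intensities[s] for s in sources])
    P = solve_lyapunov(cl.sys.A, Bn @ Bn.T)
    rows = [cl.output_index[o] for o in outputs]
    C = cl.sys.C[rows, :]
    if np.any(cl.sys.D[rows][:, cols] != 0):
        raise SynthesisError("white-noise feedthrough: stationary variance infinite")
    return np.diag(C @ P @ C.T)


def implied_rms_error(
    plant: AugmentedPlant,
    controller: ControllerModel,
    d_series: np.ndarray,
    constants: TaskConstants | None = None,
) -> float:
    """Model-implied RMS cursor error for a known perturbation series.

    Combines the deterministic closed-loop response to the recorded d (zero
    initial conditions, warm-up discarded) with the stationary variance
    contributed by endogenous noise, as a root sum of squares.
    """
    constants = constants or plant.constants
    cl = closed_loop(plant, controller)
    if not cl.sys.is_stable():
        raise SynthesisError("closed loop unstable")
    d = np.asarray(d_series, dtype=float)
    dsys = discretize_zoh(cl.sys, constants.dt)
    U = np.zeros((d.size, cl.sys.n_inputs))
    U[:, cl.input_index["d_ext"]] = d
    Y = simulate(dsys, U)
    e_det = Y[:, cl.output_index["e"]]
    nskip = max(0, e_det.size - constants.n_keep)
    e_det = e_det[nskip:]
    rms_det_sq = float(np.mean(e_det ** 2))
    if plant.params.noise_intensity > 0:
        var_stoch = float(
            stationary_output_variance(cl, constants, plant.params,
                                       outputs=("e",), sources=("n_w",))[0]
        )
    else:
        var_stoch = 0.0
    return math.sqrt(rms_det_sq + var_stoch)
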