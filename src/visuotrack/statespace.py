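"""Minimal continuous-time linear-systems toolbox.

Every subsystem in the tracking model -- the cursor integrator, the
perturbation and endogenous-noise prefilters, the Pade delay, the LQG
controller, and their interconnections -- is represented by one plain
container, :class:`StateSpaceModel`, holding the standard (A, B, C, D)
realization.  Functions in this module construct, interconnect, analyze and
simulate such systems; the heavy numerics (Riccati, Lyapunov, matrix
exponential) are delegated to :mod:`scipy.linalg` with explicit residual
checks so that failures surface as errors rather than bad designs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg


class DimensionError(ValueError):
    """Incompatible port or state dimensions in an interconnection."""


class SynthesisError(RuntimeError):
    """A Riccati/Lyapunov/balancing computation failed or is ill-posed."""


def _as_2d(M, name: str) -> np.ndarray:
    M = np.atleast_2d(np.asarray(M, dtype=float))
    if not np.all(np.isfinite(M)):
        raise ValueError(f"{name} contains non-finite entries")
    return M


@dataclass
class StateSpaceModel:
    """Continuous-time linear system  dx/dt = A x + B u,  y = C x + D u.

    Parameters
    ----------
    A : (n, n) array
        State dynamics matrix (units 1/s on each state).
    B : (n, m) array
        Input matrix.
    C : (p, n) array
        Output matrix.
    D : (p, m) array
        Feedthrough.
    state_labels : list of str, optional
        Symbolic names for the states, propagated through interconnections.
    """

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    state_labels: list = field(default_factory=list)

    def __post_init__(self):
        self.A = _as_2d(self.A, "A")
        self.B = _as_2d(self.B, "B")
        self.C = _as_2d(self.C, "C")
        self.D = _as_2d(self.D, "D")
        n = self.A.shape[0]
        if self.A.shape[1] != n:
            raise DimensionError(f"A must be square, got {self.A.shape}")
        if n == 0:
            # static system: B is (0, m), C is (p, 0); D fixes the port sizes
            self.B = self.B.reshape(0, self.D.shape[1])
            self.C = self.C.reshape(self.D.shape[0], 0)
        if self.B.shape[0] != n:
            raise DimensionError(f"B has {self.B.shape[0]} rows, expected n={n}")
        if self.C.shape[1] != n:
            raise DimensionError(f"C has {self.C.shape[1]} cols, expected n={n}")
        if self.D.shape != (self.C.shape[0], self.B.shape[1]):
            raise DimensionError(
                f"D shape {self.D.shape} inconsistent with C rows/B cols "
                f"({self.C.shape[0]}, {self.B.shape[1]})"
            )
        if not self.state_labels:
            self.state_labels = [f"x{i}" for i in range(n)]
        if len(self.state_labels) != n:
            raise DimensionError("state_labels length must equal state dimension")

    @property
    def n_states(self) -> int:
        return self.A.shape[0]

    @property
    def n_inputs(self) -> int:
        return self.B.shape[1]

    @property
    def n_outputs(self) -> int:
        return self.C.shape[0]

    def poles(self) -> np.ndarray:
        if self.n_states == 0:
            return np.array([])
        return linalg.eigvals(self.A)

    def is_stable(self, margin: float = 0.0) -> bool:
        if self.n_states == 0:
            return True
        return bool(np.max(self.poles().real) < -margin)

    def to_json(self) -> str:
        return json.dumps(
            {
                "A": self.A.tolist(),
                "B": self.B.tolist(),
                "C": self.C.tolist(),
                "D": self.D.tolist(),
                "state_labels": list(self.state_labels),
            }
        )

    @classmethod
    def from_json(cls, s: str) -> "StateSpaceModel":
        d = json.loads(s)
        return cls(
            np.array(d["A"]), np.array(d["B"]), np.array(d["C"]), np.array(d["D"]),
            state_labels=list(d["state_labels"]),
        )


@dataclass
class FrequencyResponse:
    """Complex frequency response on an ascending positive grid of rad/s."""

    omega: np.ndarray
    values: np.ndarray  # shape (n_freq, p, m)

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=float)
        self.values = np.asarray(self.values, dtype=complex)
        if self.omega.ndim != 1 or np.any(self.omega <= 0):
            raise ValueError("omega must be a 1-D positive vector")
        if np.any(np.diff(self.omega) <= 0):
            raise ValueError("omega must be strictly increasing")
        if self.values.shape[0] != self.omega.size:
            raise DimensionError("one response block per frequency required")

    def siso(self) -> np.ndarray:
        """Return the scalar response as a 1-D complex vector (SISO only)."""
        if self.values.shape[1:] != (1, 1):
            raise DimensionError("siso() requires a 1x1 response")
        return self.values[:, 0, 0]


def identity_system(m: int = 1) -> StateSpaceModel:
    """Static unity system with ``m`` inputs/outputs and no states."""
    return StateSpaceModel(
        np.zeros((0, 0)), np.zeros((0, m)), np.zeros((m, 0)), np.eye(m),
        state_labels=[],
    )


def series(sys1: StateSpaceModel, sys2: StateSpaceModel) -> StateSpaceModel:
    """Cascade ``sys2 * sys1`` (signal flows sys1 -> sys2)."""
    if sys1.n_outputs != sys2.n_inputs:
        raise DimensionError(
            f"series: sys1 has {sys1.n_outputs} outputs but sys2 expects "
            f"{sys2.n_inputs} inputs"
        )
    n1, n2 = sys1.n_states, sys2.n_states
    A = np.block(
        [
            [sys1.A, np.zeros((n1, n2))],
            [sys2.B @ sys1.C, sys2.A],
        ]
    )
    B = np.vstack([sys1.B, sys2.B @ sys1.D])
    C = np.hstack([sys2.D @ sys1.C, sys2.C])
    D = sys2.D @ sys1.D
    return StateSpaceModel(
        A, B, C, D, state_labels=list(sys1.state_labels) + list(sys2.state_labels)
    )


def parallel_sum(sys1: StateSpaceModel, sys2: StateSpaceModel) -> StateSpaceModel:
    """Output sum of two systems sharing the same input."""
    if sys1.n_inputs != sys2.n_inputs or sys1.n_outputs != sys2.n_outputs:
        raise DimensionError("parallel_sum: port dimensions must match")
    n1, n2 = sys1.n_states, sys2.n_states
    A = np.block([[sys1.A, np.zeros((n1, n2))], [np.zeros((n2, n1)), sys2.A]])
    B = np.vstack([sys1.B, sys2.B])
    C = np.hstack([sys1.C, sys2.C])
    return StateSpaceModel(
        A, B, C, sys1.D + sys2.D,
        state_labels=list(sys1.state_labels) + list(sys2.state_labels),
    )


def feedback_loop(
    plant: StateSpaceModel, controller: StateSpaceModel, sign: int = -1
) -> StateSpaceModel:
    """Close a feedback loop of ``controller`` around ``plant``.

    The controller reads the first ``controller.n_inputs`` outputs of the
    plant and injects ``sign * controller_output`` into the first
    ``controller.n_outputs`` inputs of the plant.  All plant inputs remain
    available as exogenous injection points of the closed loop, and all plant
    outputs are retained, so the returned system maps the plant's original
    input ports to its original output ports with the loop closed.
    """
    if sign not in (-1, 1):
        raise ValueError("sign must be +1 or -1")
    ny, nu = controller.n_inputs, controller.n_outputs
    if ny > plant.n_outputs:
        raise DimensionError(
            f"feedback: controller expects {ny} measurements but plant provides "
            f"{plant.n_outputs} outputs"
        )
    if nu > plant.n_inputs:
        raise DimensionError(
            f"feedback: controller drives {nu} actuators but plant accepts "
            f"{plant.n_inputs} inputs"
        )
    npx, ncx = plant.n_states, controller.n_states
    m, p = plant.n_inputs, plant.n_outputs

    # y = Cp xp + Dp (r + s*Eu*(Cc xc + Dc*Ey*y));  Eu/Ey embed controller ports
    Eu = np.zeros((m, nu))
    Eu[:nu, :] = np.eye(nu)
    Ey = np.zeros((ny, p))
    Ey[:, :ny] = np.eye(ny)

    M = np.eye(p) - sign * plant.D @ Eu @ controller.D @ Ey
    try:
        Minv = linalg.inv(M)
    except linalg.LinAlgError as exc:  # pragma: no cover - degenerate algebra
        raise DimensionError("algebraic loop: I - D_p D_c not invertible") from exc
    if np.linalg.cond(M) > 1e12:
        raise DimensionError("algebraic loop: feedthrough coupling nearly singular")

    Cp_eff = Minv @ np.hstack([plant.C, sign * plant.D @ Eu @ controller.C])
    Dp_eff = Minv @ plant.D
    # closed-loop output y as function of [xp; xc] and exogenous r
    A = np.block(
        [
            [plant.A, np.zeros((npx, ncx))],
            [np.zeros((ncx, npx)), controller.A],
        ]
    ) + np.vstack([sign * plant.B @ Eu @ controller.D @ Ey, controller.B @ Ey]) @ Cp_eff
    A[:npx, npx:] += sign * plant.B @ Eu @ controller.C
    B = (
        np.vstack([plant.B, np.zeros((ncx, m))])
        + np.vstack([sign * plant.B @ Eu @ controller.D @ Ey, controller.B @ Ey])
        @ Dp_eff
    )
    return StateSpaceModel(
        A,
        B,
        Cp_eff,
        Dp_eff,
        state_labels=list(plant.state_labels) + list(controller.state_labels),
    )


def pade_delay(tau: float, order: int = 4) -> StateSpaceModel:
    """All-pass Pade approximation of a pure delay ``exp(-s*tau)``.

    Uses the diagonal (order, order) Pade table entry, whose magnitude is
    exactly one at every real frequency.
    """
    if tau < 0:
        raise ValueError("delay tau must be nonnegative")
    if order < 1:
        raise ValueError("order must be >= 1")
    if tau == 0:
        return identity_system(1)
    k = np.arange(order + 1)
    from scipy.special import factorial

    # coefficients of the diagonal Pade approximant:
    #   den(s) = sum_k c_k (tau s)^k,  num(s) = den(-s)
    c = factorial(2 * order - k) * factorial(order) / (
        factorial(2 * order) * factorial(k) * factorial(order - k)
    )
    den = c * tau ** k          # ascending powers of s
    num = den * (-1.0) ** k
    from scipy.signal import tf2ss

    A, B, C, D = tf2ss(num[::-1], den[::-1])
    return StateSpaceModel(
        A, B, C, D, state_labels=[f"delay{i+1}" for i in range(order)]
    )


def solve_care(A, B, Q, R, S=None) -> np.ndarray:
    """Stabilizing solution of A'P + PA - (PB+S) R^-1 (PB+S)' + Q = 0."""
    A = _as_2d(A, "A")
    B = _as_2d(B, "B")
    Q = _as_2d(Q, "Q")
    R = _as_2d(R, "R")
    if np.min(linalg.eigvalsh(R)) <= 0:
        raise SynthesisError("R must be positive definite")
    try:
        P = linalg.solve_continuous_are(A, B, Q, R, s=S)
    except Exception as exc:
        raise SynthesisError(f"Riccati solve failed: {exc}") from exc
    Sm = np.zeros_like(B) if S is None else _as_2d(S, "S")
    G = (P @ B + Sm) @ linalg.solve(R, (P @ B + Sm).T)
    resid = A.T @ P + P @ A - G + Q
    if np.linalg.norm(resid) > 1e-8 * (1.0 + np.linalg.norm(A)) * (
        1.0 + np.linalg.norm(P)
    ):
        raise SynthesisError(
            f"Riccati residual too large: {np.linalg.norm(resid):.3e}"
        )
    K = linalg.solve(R, (P @ B + Sm).T)
    if A.shape[0] and np.max(linalg.eigvals(A - B @ K).real) >= 0:
        raise SynthesisError("Riccati solution is not stabilizing")
    return P


def solve_lyapunov(A, Q) -> np.ndarray:
    """Solve A P + P A' + Q = 0 for a Hurwitz A and PSD Q."""
    A = _as_2d(A, "A")
    Q = _as_2d(Q, "Q")
    if np.max(linalg.eigvals(A).real) >= 0:
        raise SynthesisError("A must be Hurwitz: Gramian undefined for unstable A")
    P = linalg.solve_continuous_lyapunov(A, -Q)
    resid = A @ P + P @ A.T + Q
    if np.linalg.norm(resid) > 1e-9 * (1.0 + np.linalg.norm(A)) * (
        1.0 + np.linalg.norm(P)
    ):
        raise SynthesisError(
            f"Lyapunov residual too large: {np.linalg.norm(resid):.3e}"
        )
    return 0.5 * (P + P.T)


def gramians(sys: StateSpaceModel) -> tuple[np.ndarray, np.ndarray]:
    """Controllability and observability Gramians of a stable system."""
    if not sys.is_stable():
        raise SynthesisError("Gramians require an asymptotically stable system")
    Wc = solve_lyapunov(sys.A, sys.B @ sys.B.T)
    Wo = solve_lyapunov(sys.A.T, sys.C.T @ sys.C)
    return Wc, Wo


def balanced_hsv(sys: StateSpaceModel) -> np.ndarray:
    """Hankel singular values, descending.

    Computed from an eigen-factorization of the controllability Gramian:
    sigma_i = sqrt(eig(Wc Wo)).  Values below ``1e-12 * sigma_1`` are floored
    to zero (numerically unobservable/uncontrollable directions).
    """
    Wc, Wo = gramians(sys)
    # symmetric factor of Wc (robust to semidefiniteness, unlike Cholesky)
    lam, U = linalg.eigh(Wc)
    lam = np.clip(lam, 0.0, None)
    F = U * np.sqrt(lam)
    sv = linalg.svdvals(F.T @ Wo @ F)
    hsv = np.sqrt(np.clip(sv, 0.0, None))
    hsv = np.sort(hsv)[::-1]
    if hsv.size and hsv[0] > 0:
        hsv[hsv < 1e-12 * hsv[0]] = 0.0
    return hsv


def frequency_response(sys: StateSpaceModel, omega_grid) -> FrequencyResponse:
    """Evaluate C (iw I - A)^-1 B + D on a positive ascending grid."""
    omega = np.asarray(omega_grid, dtype=float)
    n = sys.n_states
    vals = np.empty((omega.size, sys.n_outputs, sys.n_inputs), dtype=complex)
    if n == 0:
        vals[:] = sys.D
        return FrequencyResponse(omega, vals)
    poles = linalg.eigvals(sys.A)
    dist = np.min(np.abs(1j * omega[:, None] - poles[None, :]), axis=1)
    bad = dist < 1e-9 * np.maximum(1.0, omega)
    if np.any(bad):
        w = omega[np.argmax(bad)]
        raise SynthesisError(
            f"marginal pole at frequency {w:g} rad/s: response undefined"
        )
    # batched direct solves: robust for defective A (repeated poles), and a
    # single LAPACK batch call over the whole grid
    M = (1j * omega)[:, None, None] * np.eye(n) - sys.A[None, :, :]
    X = np.linalg.solve(M, np.broadcast_to(sys.B.astype(complex),
                                           (omega.size, n, sys.n_inputs)))
    vals = sys.C @ X + sys.D
    return FrequencyResponse(omega, vals)


@dataclass
class DiscreteStateSpace:
    """Zero-order-hold discretization of a continuous system."""

    A: np.ndarray
    B: np.ndarray
    C: np.ndarray
    D: np.ndarray
    dt: float


def discretize_zoh(sys: StateSpaceModel, dt: float) -> DiscreteStateSpace:
    """Exact zero-order-hold discretization via the block matrix exponential."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    n, m = sys.n_states, sys.n_inputs
    if n == 0:
        return DiscreteStateSpace(sys.A.copy(), sys.B.copy(), sys.C.copy(),
                                  sys.D.copy(), dt)
    M = np.zeros((n + m, n + m))
    M[:n, :n] = sys.A * dt
    M[:n, n:] = sys.B * dt
    E = linalg.expm(M)
    return DiscreteStateSpace(E[:n, :n], E[:n, n:], sys.C.copy(), sys.D.copy(), dt)


def simulate(dsys: DiscreteStateSpace, inputs: np.ndarray,
             x0: np.ndarray | None = None) -> np.ndarray:
    """Run a discrete-time simulation; ``inputs`` is (n_samples, m)."""
    U = np.atleast_2d(np.asarray(inputs, dtype=float))
    if U.shape[1] != dsys.B.shape[1]:
        if U.shape[0] == dsys.B.shape[1]:
            U = U.T
        else:
            raise DimensionError("input sequence has wrong width")
    n = dsys.A.shape[0]
    x = np.zeros(n) if x0 is None else np.asarray(x0, dtype=float).copy()
    Y = np.empty((U.shape[0], dsys.C.shape[0]))
    for k in range(U.shape[0]):
        Y[k] = dsys.C @ x + dsys.D @ U[k]
        x = dsys.A @ x + dsys.B @ U[k]
    return Y
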