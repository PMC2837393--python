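"""Controller complexity (Hankel singular values) and cohort statistics.

The complexity of a fitted control strategy is measured by the Hankel
singular values of the LQG controller viewed as a standalone stable system
from the delayed-error measurement to the ideal control output: the
controllability Gramian is driven through the Kalman gain L, the
observability Gramian is read out through the LQR gain K, and the HSVs of
the balanced realization count the dynamically significant states.  HSVs
are normalized per subject by that subject's mean first HSV so that gross
gain differences do not masquerade as complexity.

Group comparisons use Welch two-tailed t-tests on one value per subject
(per-subject means), never on pooled trials.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import TrialRecord, rms_metrics
from .plant import ControllerModel, SubjectParameters, TaskConstants
from .statespace import SynthesisError, balanced_hsv


@dataclass
class HsvProfile:
    """Hankel singular values of one fitted controller."""

    subject_id: str
    trial_index: int
    hsvs: np.ndarray
    normalized_hsvs: np.ndarray | None = None

    def __post_init__(self):
        self.hsvs = np.asarray(self.hsvs, dtype=float)
        if np.any(self.hsvs < 0) or np.any(np.diff(self.hsvs) > 1e-12):
            raise ValueError("HSVs must be nonnegative and descending")


def controller_hsvs(
    controller: ControllerModel, subject_id: str = "", trial_index: int = 0
) -> HsvProfile:
    """HSVs of the controller as a system from measurement y to u_ideal."""
    if not controller.sys.is_stable():
        raise SynthesisError(
            "controller is not stable as a standalone system; HSVs undefined"
        )
    return HsvProfile(
        subject_id=subject_id,
        trial_index=trial_index,
        hsvs=balanced_hsv(controller.sys),
    )


def normalize_profiles(profiles: list[HsvProfile]) -> list[HsvProfile]:
    """Normalize each subject's HSVs by that subject's mean first HSV."""
    by_subject: dict[str, list[HsvProfile]] = {}
    for p in profiles:
        by_subject.setdefault(p.subject_id, []).append(p)
    out = []
    for sid, plist in by_subject.items():
        mean_first = float(np.mean([p.hsvs[0] for p in plist]))
        if mean_first <= 0:
            raise ValueError(f"subject {sid}: degenerate first HSV")
        for p in plist:
            out.append(
                HsvProfile(
                    subject_id=p.subject_id,
                    trial_index=p.trial_index,
                    hsvs=p.hsvs,
                    normalized_hsvs=p.hsvs / mean_first,
                )
            )
    return out


def derived_noise_measure(
    params: SubjectParameters, ms_udot: float
) -> float:
    """log10 of endogenous-noise power relative to control-velocity power.

    bandwidth * intensity / MS(udot); zero intensity maps to -inf.
    """
    if ms_udot <= 0:
        raise ValueError("mean-square control velocity must be positive")
    val = params.noise_bandwidth * params.noise_intensity / ms_udot
    if val == 0.0:
        return -math.inf
    return math.log10(val)


@dataclass
class CohortSummary:
    """Per-group statistics and Welch tests on per-subject means."""

    n_young: int
    n_elderly: int
    measures: dict = field(default_factory=dict)
    # measures[name] = dict(mean_young, mean_elderly, sd_young, sd_elderly,
    #                       t, df, p)


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch two-tailed t-test; returns (t, df, p)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two subjects per group")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return 0.0, float(a.size + b.size - 2), 1.0
        raise ValueError("degenerate variance with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    sa, sb = va / a.size, vb / b.size
    df = (sa + sb) ** 2 / (sa ** 2 / (a.size - 1) + sb ** 2 / (b.size - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def cohort_tests(
    per_subject_young: dict[str, np.ndarray],
    per_subject_elderly: dict[str, np.ndarray],
) -> CohortSummary:
    """Welch tests on every shared per-subject measure.

    Inputs map measure name -> vector of per-subject means (one entry per
    subject).  Every p-value is computed from exactly one value per subject.
    """
    names = sorted(set(per_subject_young) & set(per_subject_elderly))
    if not names:
        raise ValueError("no shared measures between groups")
    ny = {len(v) for v in per_subject_young.values()}
    ne = {len(v) for v in per_subject_elderly.values()}
    if len(ny) != 1 or len(ne) != 1:
        raise ValueError("inconsistent subject counts across measures")
    summary = CohortSummary(n_young=ny.pop(), n_elderly=ne.pop())
    for name in names:
        a = np.asarray(per_subject_young[name], dtype=float)
        b = np.asarray(per_subject_elderly[name], dtype=float)
        t, df, p = welch_test(a, b)
        summary.measures[name] = dict(
            mean_young=float(a.mean()),
            mean_elderly=float(b.mean()),
            sd_young=float(a.std(ddof=1)),
            sd_elderly=float(b.std(ddof=1)),
            t=t, df=df, p=p,
        )
    return summary


@dataclass
class SlowingCase:
    """One model x parameter x scale cell of the noise-increase experiment."""

    subject_id: str
    parameter: str
    scale: float
    h_ud_mag: np.ndarray          # |H_ud| on the report grid
    crosscorr_latency: float | None
    synthesis_failed: bool = False


def slowing_experiment(
    fitted_models: list[tuple[str, SubjectParameters]],
    constants: TaskConstants,
    scale_factors: tuple[float, ...] = (4.0,),
    parameters: tuple[str, ...] = (
        "noise_intensity", "noise_bandwidth", "rho",
    ),
    omega_grid: np.ndarray | None = None,
    d_list: list[np.ndarray] | None = None,
    seed: int = 0,
) -> list[SlowingCase]:
    """Increase each noise-related parameter and re-examine the response.

    For each fitted model and each parameter scaled by each factor, the LQG
    design is recomputed and |H_ud| reported on the grid; if perturbation
    sequences are supplied, trials are re-simulated and the cross-correlation
    latency re-estimated.  A scale of 1.0 reproduces the baseline.
    """
    from .plant import assemble_plant, design_lqg, predicted_response
    from .cohort import simulate_subject
    from .latency import trial_latency, NoResponseError

    if omega_grid is None:
        omega_grid = np.array([1.0, 2.0, 5.0, 10.0, 20.0])
    cases = []
    for i, (sid, params) in enumerate(fitted_models):
        for pname in parameters:
            for scale in scale_factors:
                mod = params.replace(**{pname: getattr(params, pname) * scale})
                try:
                    plant = assemble_plant(constants, mod)
                    ctrl = design_lqg(plant)
                    H, _ = predicted_response(plant, ctrl, omega_grid, constants)
                    mag = np.abs(H.siso())
                except SynthesisError:
                    cases.append(SlowingCase(sid, pname, scale,
                                             np.array([]), None, True))
                    continue
                lat = None
                if d_list is not None:
                    trials = simulate_subject(
                        constants, mod, d_list, seed=seed + 7919 * i,
                        subject_id=sid, controller=ctrl,
                    )
                    lats = []
                    for tr in trials:
                        try:
                            lats.append(trial_latency(tr, constants))
                        except (NoResponseError, ValueError):
                            pass
                    lat = float(np.mean(lats)) if lats else None
                cases.append(SlowingCase(sid, pname, scale, mag, lat))
    return cases
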