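"""Synthetic-cohort generator: the simulated counterpart of the experiment.

Emulates the trial protocol -- ten 60-second trials per subject at 100 Hz,
first 9 s discarded, the same band-limited Gaussian perturbation sequences
for every subject -- with each subject realized as a closed loop of the
LQG-optimal controller (designed for that subject's four parameters) around
the true task dynamics.  Two deliberate world/model mismatches are kept: the
simulated latency is a true integer-sample delay (the controller's internal
model uses the Pade approximation), and the endogenous noise is sampled per
step rather than being an exact continuous-time process.

Cohort parameters are drawn per subject from log10-normal statistics
(young/elderly group means and SDs of latency, noise intensity, noise
bandwidth and rho).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np

from .plant import (
    SubjectParameters,
    TaskConstants,
    assemble_plant,
    build_noise_filter,
    design_lqg,
    ControllerModel,
)
from .statespace import discretize_zoh

#: Group statistics of the base-10 logarithms of the four subject parameters
#: (means per group; one aggregate SD and the median intra-subject SD per
#: parameter).  These are the generative defaults for synthetic cohorts.
LOG10_GROUP_MEANS = {
    "young": {
        "latency_tau": -0.5879,
        "noise_intensity": -2.7556,
        "noise_bandwidth": 0.9495,
        "rho": -0.7257,
    },
    "elderly": {
        "latency_tau": -0.6252,
        "noise_intensity": -2.6408,
        "noise_bandwidth": 0.9039,
        "rho": -0.3010,
    },
}
LOG10_SDS = {
    "latency_tau": 0.1109,
    "noise_intensity": 0.5756,
    "noise_bandwidth": 0.2713,
    "rho": 0.4552,
}
#: Median intra-subject SDs of the same log10 quantities (trial-to-trial
#: repeatability of per-trial fits within one subject).
LOG10_MISSD = {
    "latency_tau": 0.0268,
    "noise_intensity": 0.4205,
    "noise_bandwidth": 0.2428,
    "rho": 0.1817,
}

PARAM_ORDER = ("latency_tau", "noise_intensity", "noise_bandwidth", "rho")


@dataclass
class TrialRecord:
    """One trial's sampled perturbation, control input and cursor error."""

    subject_id: str
    trial_index: int          # 1-based, 1..10
    t: np.ndarray             # s
    d: np.ndarray             # perturbation
    u: np.ndarray             # control input
    e: np.ndarray             # displayed cursor error
    sample_rate: float
    warmup_discarded: bool = True

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.d = np.asarray(self.d, dtype=float)
        self.u = np.asarray(self.u, dtype=float)
        self.e = np.asarray(self.e, dtype=float)
        n = self.t.size
        if not (self.d.size == self.u.size == self.e.size == n):
            raise ValueError("t, d, u, e must have equal lengths")

    @property
    def n_samples(self) -> int:
        return self.t.size

    def integral_residual(self) -> float:
        """Max deviation of e from the running integral of u + d (self-check)."""
        dt = 1.0 / self.sample_rate
        e_rec = self.e[0] + dt * np.concatenate(
            [[0.0], np.cumsum(self.u[:-1] + self.d[:-1])]
        )
        return float(np.max(np.abs(e_rec - self.e)))

    def to_csv(self, path) -> None:
        header = (
            f"# subject_id={self.subject_id} trial_index={self.trial_index} "
            f"sample_rate={self.sample_rate:g} "
            f"warmup_discarded={int(self.warmup_discarded)}\n"
            "t,d,u,e\n"
        )
        body = "\n".join(
            f"{t:.6f},{d:.9g},{u:.9g},{e:.9g}"
            for t, d, u, e in zip(self.t, self.d, self.u, self.e)
        )
        with open(path, "w") as fh:
            fh.write(header + body + "\n")

    @classmethod
    def from_csv(cls, path) -> "TrialRecord":
        with open(path) as fh:
            meta_line = fh.readline().strip().lstrip("# ")
            meta = dict(kv.split("=") for kv in meta_line.split())
            arr = np.loadtxt(fh, delimiter=",", skiprows=1)
        return cls(
            subject_id=meta["subject_id"],
            trial_index=int(meta["trial_index"]),
            t=arr[:, 0], d=arr[:, 1], u=arr[:, 2], e=arr[:, 3],
            sample_rate=float(meta["sample_rate"]),
            warmup_discarded=bool(int(meta["warmup_discarded"])),
        )


@dataclass
class CohortSpec:
    """Generative specification of one synthetic cohort."""

    group: str                      # "young" or "elderly"
    n_subjects: int = 12
    log10_means: dict = field(default_factory=dict)
    log10_sds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.group not in LOG10_GROUP_MEANS:
            raise ValueError("group must be 'young' or 'elderly'")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        means = dict(LOG10_GROUP_MEANS[self.group])
        means.update(self.log10_means)
        self.log10_means = means
        sds = dict(LOG10_SDS)
        sds.update(self.log10_sds)
        if any(v < 0 for v in sds.values()):
            raise ValueError("log10 SDs must be nonnegative")
        self.log10_sds = sds


def sample_cohort(spec: CohortSpec) -> list[SubjectParameters]:
    """Draw independent log10-normal subject parameters per the cohort spec."""
    rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(spec.n_subjects):
        logs = {
            k: spec.log10_means[k] + spec.log10_sds[k] * rng.standard_normal()
            for k in PARAM_ORDER
        }
        out.append(SubjectParameters(**{k: 10.0 ** v for k, v in logs.items()}))
    return out


def _pert_filter_discrete(constants: TaskConstants) -> tuple[float, float]:
    """ZOH discretization (a_d, b_d) of the first-order perturbation filter."""
    wc = 2.0 * math.pi * constants.pert_cutoff
    ad = math.exp(-wc * constants.dt)
    bd = 1.0 - ad  # ZOH of unit-DC first-order lag
    return ad, bd


def generate_perturbations(
    constants: TaskConstants, n_trials: int, seed: int = 0
) -> list[np.ndarray]:
    """Generate the shared perturbation sequences for a session.

    Each trial is an independent realization of discrete white Gaussian noise
    (variance ``pert_white_intensity * sample_rate``) passed through the
    ZOH-discretized first-order perturbation filter.  All subjects of a
    session receive the same list, exactly as in the protocol.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    n = round(constants.trial_length * constants.sample_rate)
    ad, bd = _pert_filter_discrete(constants)
    sigma_w = math.sqrt(constants.pert_white_intensity * constants.sample_rate)
    trials = []
    from scipy.signal import lfilter

    for _ in range(n_trials):
        w = sigma_w * rng.standard_normal(n)
        # state recursion x[k+1] = ad x[k] + bd w[k], d[k] = x[k], x[0] = 0
        x = lfilter([bd], [1.0, -ad], w)
        d = np.concatenate([[0.0], x[:-1]])
        trials.append(d)
    return trials


def calibrate_pert_intensity(
    constants: TaskConstants,
    target_time: float = 10.0,
    tolerance: float = 1.0,
    n_sims: int = 200,
    seed: int = 12345,
) -> float:
    """White-source intensity making an uncorrected cursor leave the screen
    in ``target_time`` seconds (median first-passage time over simulations).

    Bisection on the intensity; all bisection iterates reuse one set of
    unit-intensity perturbation realizations, so the procedure is exact up to
    Monte-Carlo error of the shared sample.
    """
    base = TaskConstants(**{**asdict(constants), "pert_white_intensity": 1.0})
    sims = generate_perturbations(base, n_sims, seed=seed)
    dt = base.dt
    # open loop (u = 0): e is the running integral of d; scale ~ sqrt(q)
    abs_e = [np.abs(dt * np.cumsum(d)) for d in sims]

    def median_fpt(q: float) -> float:
        thresh = constants.screen_halfwidth / math.sqrt(q)
        times = []
        for e in abs_e:
            idx = np.argmax(e >= thresh)
            if e[idx] >= thresh:
                times.append((idx + 1) * dt)
            else:
                times.append(np.inf)   # censored at trial end
        return float(np.median(times))

    lo, hi = 1e-6, 10.0
    if not (median_fpt(hi) <= target_time <= median_fpt(lo)):
        raise RuntimeError("calibration bracket does not contain the target")
    for _ in range(200):
        mid = math.sqrt(lo * hi)
        t = median_fpt(mid)
        if abs(t - target_time) <= 0.5 * tolerance:
            return mid
        if t > target_time:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-12:
            break
    raise RuntimeError("bisection on perturbation intensity did not converge")


def simulate_subject(
    constants: TaskConstants,
    params: SubjectParameters,
    d_list: list[np.ndarray],
    seed: int = 0,
    subject_id: str = "S0",
    controller: ControllerModel | None = None,
) -> list[TrialRecord]:
    """Simulate one subject's session over the given perturbation list.

    The world is simulated at the sample rate: the cursor integrates
    ``u + d`` exactly (both held over each step), the displayed error is
    delayed by a true integer-sample latency, and the subject's discretized
    LQG controller closes the loop.  Endogenous noise is white per-step
    Gaussian input to the subject's second-order noise filter, added to the
    ideal control output.  The warm-up is discarded from the returned
    records.
    """
    rng = np.random.default_rng(seed)
    plant = assemble_plant(constants, params)
    if controller is None:
        controller = design_lqg(plant)
    dt = constants.dt
    # Tustin keeps the controller's instantaneous response to the displayed
    # error (the continuous controller has no sample-and-hold lag)
    from scipy.signal import cont2discrete

    Ac, Bc_, Cc_, Dc_, _ = cont2discrete(
        (controller.sys.A, controller.sys.B, controller.sys.C,
         controller.sys.D), dt, method="bilinear",
    )
    Bc, Cc, Dc = Bc_[:, 0], Cc_[0], float(Dc_[0, 0])
    noise_d = discretize_zoh(build_noise_filter(params.noise_bandwidth), dt)
    m = round(params.latency_tau * constants.sample_rate)
    sigma_n = math.sqrt(params.noise_intensity * constants.sample_rate)

    An, Bn, Cn = noise_d.A, noise_d.B[:, 0], noise_d.C[0]
    n_keep = constants.n_keep

    records = []
    for ti, d in enumerate(d_list, start=1):
        n = d.size
        wn = sigma_n * rng.standard_normal(n)
        xc = np.zeros(Ac.shape[0])
        xn = np.zeros(2)
        e_hist = np.zeros(n + 1)
        u_arr = np.empty(n)
        for k in range(n):
            y = e_hist[k - m] if k >= m else 0.0
            u = Cc @ xc + Dc * y + Cn @ xn
            u_arr[k] = u
            e_hist[k + 1] = e_hist[k] + dt * (u + d[k])
            xc = Ac @ xc + Bc * y
            xn = An @ xn + Bn * wn[k]
        sl = slice(n - n_keep, n)
        t = np.arange(n)[sl] * dt
        records.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=ti,
                t=t,
                d=d[sl],
                u=u_arr[sl],
                e=e_hist[:-1][sl],
                sample_rate=constants.sample_rate,
            )
        )
    return records


def rms_metrics(trial: TrialRecord) -> tuple[float, float]:
    """RMS cursor error and RMS control-input velocity of one trial.

    The input velocity is the first difference of u scaled by the sample
    rate (the discrete derivative).
    """
    if not trial.warmup_discarded:
        raise ValueError("rms_metrics expects warm-up-discarded trials")
    rms_e = float(np.sqrt(np.mean(trial.e ** 2)))
    udot = np.diff(trial.u) * trial.sample_rate
    rms_udot = float(np.sqrt(np.mean(udot ** 2)))
    return rms_e, rms_udot


@dataclass
class SyntheticSubject:
    """Truth and data for one simulated subject."""

    subject_id: str
    group: str
    params: SubjectParameters
    trials: list


def generate_cohort_dataset(
    constants: TaskConstants,
    specs: list[CohortSpec],
    n_trials: int = 10,
    pert_seed: int = 1000,
) -> list[SyntheticSubject]:
    """Full synthetic experiment: shared perturbations, simulated sessions.

    Every subject (across all cohorts) receives the same perturbation
    sequences in the same order; subject noise realizations differ.
    """
    d_list = generate_perturbations(constants, n_trials, seed=pert_seed)
    subjects = []
    counter = 0
    for spec in specs:
        for params in sample_cohort(spec):
            counter += 1
            sid = f"{spec.group[0].upper()}{counter:02d}"
            trials = simulate_subject(
                constants, params, d_list,
                seed=spec.seed * 100003 + counter, subject_id=sid,
            )
            subjects.append(
                SyntheticSubject(subject_id=sid, group=spec.group,
                                 params=params, trials=trials)
            )
    return subjects


def write_cohort_manifest(subjects: list[SyntheticSubject], path) -> None:
    """JSON manifest of subject ids, groups and true generating parameters."""
    manifest = [
        {
            "subject_id": s.subject_id,
            "group": s.group,
            "params": asdict(s.params),
            "n_trials": len(s.trials),
        }
        for s in subjects
    ]
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def write_subject_hdf5(subjects: list[SyntheticSubject], path) -> None:
    """Write all subjects' trials into one HDF5 file (one group per subject)."""
    import h5py

    with h5py.File(path, "w") as fh:
        for s in subjects:
            g = fh.create_group(s.subject_id)
            g.attrs["group"] = s.group
            for k, v in asdict(s.params).items():
                g.attrs[k] = v
            for tr in s.trials:
                tg = g.create_group(f"trial{tr.trial_index:02d}")
                tg.attrs["sample_rate"] = tr.sample_rate
                for name in ("t", "d", "u", "e"):
                    tg.create_dataset(name, data=getattr(tr, name))
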