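"""Model-free response-latency estimation by cross-correlation.

The perturbation is first whitened (exact inverse of the discrete
perturbation prefilter), then cross-correlated with the control input.
Because the subject acts to cancel the perturbation, the cross-correlation
wanders near zero at small lags and then develops a negative (corrective)
excursion; the response latency is read off as the onset corner of that
excursion.  Numerically: de-bias by the mean over acausal (negative) lags,
zero-phase smooth with a second-order 20 Hz Butterworth filter, negate so
the corrective trend is a positive bump, and locate the peak of the second
central difference (maximum curvature at the onset) inside a search window.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.signal import butter, filtfilt

from .cohort import TrialRecord, _pert_filter_discrete
from .plant import TaskConstants


class NoResponseError(RuntimeError):
    """The cross-correlation shows no corrective trend above the noise floor."""


@dataclass
class CrossCorrelation:
    """Sampled cross-correlation r(lag) between whitened d and u."""

    lags: np.ndarray        # sample indices, strictly increasing, may be < 0
    r: np.ndarray
    n_effective: int
    sample_rate: float
    smoothed: bool = False
    noise_floor: float = 0.0   # SD of r over negative lags after de-biasing

    def __post_init__(self):
        self.lags = np.asarray(self.lags)
        self.r = np.asarray(self.r, dtype=float)
        if self.lags.shape != self.r.shape:
            raise ValueError("lags and r must have equal length")
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.r)):
            raise ValueError("correlation values must be finite")


def whiten(d: np.ndarray, constants: TaskConstants) -> np.ndarray:
    """Invert the discrete perturbation prefilter to recover white innovations.

    The output is aligned so that sample ``k`` of the whitened signal is the
    innovation that first appears in ``d`` at sample ``k`` (re-filtering the
    output with the forward filter reproduces ``d`` exactly, so lag zero of a
    subsequent cross-correlation means "simultaneous with the perturbation's
    arrival on screen").
    """
    d = np.asarray(d, dtype=float)
    ad, bd = _pert_filter_discrete(constants)
    w = np.empty_like(d)
    w[0] = d[0] / bd
    w[1:] = (d[1:] - ad * d[:-1]) / bd
    return w


def refilter(d_w: np.ndarray, constants: TaskConstants) -> np.ndarray:
    """Forward application of the discrete perturbation filter (whiten^-1)."""
    from scipy.signal import lfilter

    ad, bd = _pert_filter_discrete(constants)
    return lfilter([bd], [1.0, -ad], np.asarray(d_w, dtype=float))


def cross_correlate(
    d_w: np.ndarray,
    u: np.ndarray,
    max_lag: int,
    sample_rate: float = 100.0,
) -> CrossCorrelation:
    """Normalized cross-correlation r_j between d_w(k) and u(k+j).

    ``r`` is the mean-removed product sum divided by ``n`` and by both
    standard deviations (a correlation coefficient per lag), computed for
    ``j`` in [-max_lag, max_lag], then de-biased by subtracting the mean of
    r over the strictly negative (acausal) lags.
    """
    d_w = np.asarray(d_w, dtype=float)
    u = np.asarray(u, dtype=float)
    if d_w.size != u.size:
        raise ValueError("d_w and u must have equal lengths")
    n = d_w.size
    if n < 10 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    sd_d, sd_u = d_w.std(), u.std()
    if sd_d == 0 or sd_u == 0:
        raise ValueError("degenerate (zero-variance) input series")
    x = (d_w - d_w.mean()) / sd_d
    y = (u - u.mean()) / sd_u
    full = np.correlate(y, x, mode="full") / n   # index n-1+j <-> lag j
    lags = np.arange(-max_lag, max_lag + 1)
    r = full[n - 1 + lags]
    neg = lags < 0
    r = r - r[neg].mean()
    return CrossCorrelation(
        lags=lags,
        r=r,
        n_effective=n,
        sample_rate=sample_rate,
        smoothed=False,
        noise_floor=float(r[neg].std()),
    )


def smooth_cc(cc: CrossCorrelation, cutoff_hz: float = 20.0) -> CrossCorrelation:
    """Zero-phase (forward-backward) Butterworth smoothing of r over lag.

    Second-order filter with the cutoff expressed relative to the lag axis
    sampled at the trial sample rate.
    """
    if cc.smoothed:
        raise ValueError("cross-correlation already smoothed")
    b, a = butter(2, cutoff_hz / (cc.sample_rate / 2.0))
    r_s = filtfilt(b, a, cc.r)
    return replace(cc, r=r_s, smoothed=True,
                   noise_floor=float(r_s[cc.lags < 0].std()))


def estimate_latency(
    cc: CrossCorrelation,
    search_window: tuple[float, float] = (0.05, 0.60),
    curv_stencil: int = 5,
    peak_fraction: float = 0.8,
) -> float:
    """Latency (s) from the onset corner of the corrective trend.

    Requires a smoothed cross-correlation.  The corrective excursion must dip
    below minus three negative-lag SDs inside the window, otherwise a
    :class:`NoResponseError` is raised.

    The onset is located on the second central difference of the negated
    (corrective-positive) correlation, computed with a ``curv_stencil``-sample
    half-stencil to suppress the numerical noise that differencing amplifies.
    Because the curvature of the corrective excursion is step-like (it rises
    at the onset and stays elevated through the rise), the onset is taken as
    the first lag at which the curvature reaches ``peak_fraction`` of its
    pre-trough maximum (never below three acausal-lag curvature SDs),
    restricted to lags at or before the trough.
    """
    if not cc.smoothed:
        raise ValueError("estimate_latency expects a smoothed cross-correlation")
    lo = int(round(search_window[0] * cc.sample_rate))
    hi = int(round(search_window[1] * cc.sample_rate))
    if lo < 0 or hi <= lo:
        raise ValueError("search window must lie within positive lags")
    sel = (cc.lags >= lo) & (cc.lags <= hi)
    if not np.any(sel):
        raise ValueError("search window outside the computed lag range")
    r = cc.r
    idx = np.flatnonzero(sel)
    floor = 3.0 * cc.noise_floor
    if np.min(r[idx]) > -floor:
        raise NoResponseError(
            "no corrective trend: correlation never drops below the noise floor"
        )
    trough = idx[np.argmin(r[idx])]
    # second central difference of the corrective-positive (negated) trend
    g = -r
    h = int(curv_stencil)
    curv = np.zeros_like(g)
    curv[h:-h] = g[2 * h:] - 2.0 * g[h:-h] + g[:-2 * h]
    cand = idx[idx <= trough]
    acausal = np.flatnonzero(cc.lags < -h)
    thresh = max(
        peak_fraction * np.max(curv[cand]),
        3.0 * np.std(curv[acausal]),
    )
    above = cand[curv[cand] >= thresh]
    best = above[0] if above.size else cand[np.argmax(curv[cand])]
    return float(cc.lags[best]) / cc.sample_rate


def subject_latency(
    trials: list,
    constants: TaskConstants,
    max_lag_s: float = 1.0,
    search_window: tuple[float, float] = (0.05, 0.60),
) -> float:
    """Latency from the across-trials average cross-correlation.

    Averaging the (unsmoothed) cross-correlations of all of a subject's
    trials before smoothing suppresses the endogenous-noise floor by
    sqrt(n_trials), which keeps the onset detectable at noise levels where
    individual trials drop below the detection threshold.
    """
    if not trials:
        raise ValueError("need at least one trial")
    rs = []
    cc = None
    for tr in trials:
        d_w = whiten(tr.d, constants)
        cc = cross_correlate(
            d_w, tr.u, max_lag=int(round(max_lag_s * tr.sample_rate)),
            sample_rate=tr.sample_rate,
        )
        rs.append(cc.r)
    r_mean = np.mean(rs, axis=0)
    avg = replace(cc, r=r_mean,
                  noise_floor=float(r_mean[cc.lags < 0].std()))
    return estimate_latency(smooth_cc(avg), search_window=search_window)


def trial_latency(
    trial: TrialRecord,
    constants: TaskConstants,
    max_lag_s: float = 1.0,
    search_window: tuple[float, float] = (0.05, 0.60),
) -> float:
    """End-to-end cross-correlation latency estimate for one trial."""
    d_w = whiten(trial.d, constants)
    cc = cross_correlate(
        d_w, trial.u, max_lag=int(round(max_lag_s * trial.sample_rate)),
        sample_rate=trial.sample_rate,
    )
    return estimate_latency(smooth_cc(cc), search_window=search_window)
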