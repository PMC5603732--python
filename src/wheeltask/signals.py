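"""Trace-level operators: wheel-turn detection, dF/F, triggered averages.

Wheel velocity and per-cell fluorescence are represented as uniformly
sampled :class:`Trace` objects.  Turn detection uses hysteresis (a Schmitt
trigger) on the absolute velocity, with thresholds scaled to the trace's
robust noise level, so that noise ripple between onset and offset cannot
re-trigger an event.  dF/F uses a running-minimum baseline F0 over a long
sliding window of the smoothed trace, and a causal exponentially weighted
filter applied to the fractional change (F - F0)/F.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal as sp_signal

__all__ = [
    "Trace",
    "TurnEvents",
    "DffConfig",
    "NeuralContrastFit",
    "detect_turns",
    "compute_dff",
    "event_triggered_average",
    "EventTriggeredAverage",
    "normalize_and_sort",
    "response_amplitude",
    "fit_neural_contrast",
]


@dataclass
class Trace:
    """A uniformly sampled time series.

    kind is one of {'wheel_position', 'wheel_velocity', 'fluorescence',
    'dff'}; it is informational, not enforced against the data.
    """

    samples: np.ndarray
    sampling_rate: float
    start_time: float = 0.0
    kind: str = "wheel_velocity"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("trace samples must be one-dimensional")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace samples must be finite")
        if not (np.isfinite(self.sampling_rate) and self.sampling_rate > 0):
            raise ValueError("sampling_rate must be positive")

    @property
    def times(self) -> np.ndarray:
        return self.start_time + np.arange(len(self.samples)) / \
            self.sampling_rate

    def __len__(self) -> int:
        return len(self.samples)


@dataclass
class TurnEvents:
    """Onset/offset times (s) of detected wheel turns.

    Events strictly interleave: onset_i < offset_i < onset_{i+1}.
    """

    onsets: np.ndarray
    offsets: np.ndarray

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.offsets = np.asarray(self.offsets, dtype=float)
        if len(self.onsets) != len(self.offsets):
            raise ValueError("onsets and offsets must pair up")
        if len(self.onsets):
            merged = np.empty(2 * len(self.onsets))
            merged[0::2] = self.onsets
            merged[1::2] = self.offsets
            if not np.all(np.diff(merged) > 0):
                raise ValueError("events must strictly interleave "
                                 "(onset_i < offset_i < onset_{i+1})")

    def __len__(self) -> int:
        return len(self.onsets)


@dataclass
class DffConfig:
    """Parameters of the dF/F computation (all in seconds).

    baseline_window: length of the sliding-minimum window for F0.
    baseline_smoothing: boxcar width applied to F before the minimum.
    filter_tau: time constant of the causal exponential filter.
    centered_baseline: centered sliding-min window (else trailing/causal).
    divide_by_baseline: use (F - F0)/F0 instead of the default (F - F0)/F.
    """

    baseline_window: float = 20.0
    baseline_smoothing: float = 1.0
    filter_tau: float = 0.2
    centered_baseline: bool = True
    divide_by_baseline: bool = False

    def __post_init__(self) -> None:
        if min(self.baseline_window, self.baseline_smoothing,
               self.filter_tau) <= 0:
            raise ValueError("dF/F time constants must be positive")


# ---------------------------------------------------------------------------
# wheel turns


def smooth_trace(trace: Trace, width: float = 0.05) -> Trace:
    """Centered boxcar smoothing (width in seconds)."""
    n = max(1, int(round(width * trace.sampling_rate)))
    out = ndimage.uniform_filter1d(trace.samples, size=n, mode="nearest")
    return Trace(out, trace.sampling_rate, trace.start_time, trace.kind)


def wheel_velocity(position: Trace, smooth: float = 0.05) -> Trace:
    """Velocity from wheel position: first differences + boxcar smooth.

    The first sample is duplicated so the trace keeps its length and
    alignment; ``smooth`` is the boxcar width in seconds.
    """
    fs = position.sampling_rate
    v = np.empty_like(position.samples)
    v[1:] = np.diff(position.samples) * fs
    v[0] = v[1] if len(v) > 1 else 0.0
    out = Trace(v, fs, position.start_time, kind="wheel_velocity")
    return smooth_trace(out, smooth) if smooth > 0 else out


def robust_noise_scale(x: np.ndarray) -> float:
    """Gaussian-consistent noise scale: 1.4826 * median absolute deviation."""
    x = np.asarray(x, float)
    return float(1.4826 * np.median(np.abs(x - np.median(x))))


def detect_turns(velocity: Trace, high_thresh: float | None = None,
                 low_thresh: float | None = None, high_mult: float = 5.0,
                 low_mult: float = 2.0) -> TurnEvents:
    """Detect wheel-turn onsets/offsets with a Schmitt trigger.

    From the idle state, an onset is registered when |velocity| rises
    above ``high_thresh``; the event ends at the first later sample where
    |velocity| falls below ``low_thresh``.  The gap between the two
    thresholds is the hysteresis band that suppresses re-triggering on
    noise.  When thresholds are not given they default to ``high_mult``
    and ``low_mult`` times the trace's robust noise scale (scaled MAD),
    re-estimated per trace ("dynamic threshold").

    Events still open at the end of the trace are discarded.
    """
    if len(velocity) == 0:
        raise ValueError("empty velocity trace")
    v = np.abs(velocity.samples)
    if high_thresh is None or low_thresh is None:
        noise = robust_noise_scale(velocity.samples)
        if high_thresh is None:
            high_thresh = high_mult * noise
        if low_thresh is None:
            low_thresh = low_mult * noise
    if not (abs(high_thresh) > abs(low_thresh) >= 0):
        raise ValueError("require |high_thresh| > |low_thresh| >= 0")

    high_idx = np.flatnonzero(v > high_thresh)
    low_idx = np.flatnonzero(v < low_thresh)
    onsets, offsets = [], []
    pos = 0
    while True:
        j = np.searchsorted(high_idx, pos)
        if j == len(high_idx):
            break
        onset = high_idx[j]
        m = np.searchsorted(low_idx, onset + 1)
        if m == len(low_idx):
            break  # event never closes before the trace ends
        offset = low_idx[m]
        onsets.append(onset)
        offsets.append(offset)
        pos = offset + 1
    t0, fs = velocity.start_time, velocity.sampling_rate
    return TurnEvents(t0 + np.asarray(onsets) / fs,
                      t0 + np.asarray(offsets) / fs)


# ---------------------------------------------------------------------------
# dF/F


def _sliding_minimum(x: np.ndarray, size: int, centered: bool) -> np.ndarray:
    # positive origin shifts the window backwards in time (trailing window)
    origin = 0 if centered else (size - 1) // 2
    return ndimage.minimum_filter1d(x, size=size, mode="nearest",
                                    origin=origin)


def compute_dff(F: Trace, cfg: DffConfig | None = None) -> Trace:
    """Fractional fluorescence change relative to a running-min baseline.

    F0 is the minimum, over a sliding ``baseline_window``, of the boxcar-
    smoothed fluorescence; the output is a causal exponentially weighted
    filter (time constant ``filter_tau``) applied to (F - F0)/F.  The
    result is scale-invariant (multiplying F by a positive constant leaves
    it unchanged) and identically zero wherever F has been constant for
    longer than the window.
    """
    cfg = cfg or DffConfig()
    fs = F.sampling_rate
    x = F.samples
    if len(x) == 0:
        raise ValueError("empty fluorescence trace")

    smooth_n = max(1, int(round(cfg.baseline_smoothing * fs)))
    smoothed = ndimage.uniform_filter1d(x, size=smooth_n, mode="nearest")
    if np.any(smoothed <= 0):
        raise ValueError("smoothed fluorescence must be strictly positive")
    if np.any(x <= 0):
        raise ValueError("fluorescence must be strictly positive")

    win_n = max(1, int(round(cfg.baseline_window * fs)))
    f0 = _sliding_minimum(smoothed, win_n, cfg.centered_baseline)

    denom = f0 if cfg.divide_by_baseline else x
    frac = (x - f0) / denom

    alpha = 1.0 - np.exp(-1.0 / (cfg.filter_tau * fs))
    # first-order causal IIR, initialized at the first sample
    zi = np.array([(1.0 - alpha) * frac[0]])
    out, _ = sp_signal.lfilter([alpha], [1.0, -(1.0 - alpha)], frac, zi=zi)
    return Trace(out, fs, F.start_time, kind="dff")


# ---------------------------------------------------------------------------
# event-triggered averaging


@dataclass
class EventTriggeredAverage:
    lags: np.ndarray          # seconds relative to the event
    mean: np.ndarray
    sem: np.ndarray           # NaN when only one event contributes
    n_events: int
    n_dropped: int
    snippets: np.ndarray = field(repr=False, default=None)


def event_triggered_average(trace: Trace, event_times,
                            window=(-1.0, 2.0)) -> EventTriggeredAverage:
    """Average trace snippets aligned on event times.

    ``window`` is (t_pre, t_post) in seconds relative to each event
    (t_pre typically negative).  Events whose window extends beyond the
    trace are dropped and counted in ``n_dropped``.
    """
    t_pre, t_post = window
    if t_post <= t_pre:
        raise ValueError("window must satisfy t_pre < t_post")
    fs = trace.sampling_rate
    lag_lo = int(round(t_pre * fs))
    lag_hi = int(round(t_post * fs))
    lags = np.arange(lag_lo, lag_hi + 1)
    event_times = np.asarray(event_times, float)

    snippets, dropped = [], 0
    for t in event_times:
        i0 = int(round((t - trace.start_time) * fs))
        lo, hi = i0 + lag_lo, i0 + lag_hi
        if lo < 0 or hi >= len(trace):
            dropped += 1
            continue
        snippets.append(trace.samples[lo:hi + 1])
    if not snippets:
        raise ValueError("no event window fits fully inside the trace")
    snip = np.asarray(snippets)
    mean = snip.mean(axis=0)
    if len(snip) > 1:
        sem = snip.std(axis=0, ddof=1) / np.sqrt(len(snip))
    else:
        sem = np.full_like(mean, np.nan)
    return EventTriggeredAverage(lags / fs, mean, sem, len(snip), dropped,
                                 snippets=snip)


def normalize_and_sort(responses: np.ndarray, lags: np.ndarray,
                       sort_time: float):
    """Min-max normalize per-neuron responses and sort by a time point.

    Each row (neuron) is scaled to span [0, 1]; constant rows carry no
    shape information and are excluded with a warning.  Rows are ordered
    by descending amplitude at the lag closest to ``sort_time``.

    Returns (normalized_sorted, order, excluded) where ``order`` indexes
    the kept rows of the input and ``excluded`` lists dropped rows.
    """
    responses = np.asarray(responses, float)
    lags = np.asarray(lags, float)
    if responses.ndim != 2 or responses.shape[1] != len(lags):
        raise ValueError("responses must be (n_neurons, n_lags)")
    lo = responses.min(axis=1, keepdims=True)
    hi = responses.max(axis=1, keepdims=True)
    span = (hi - lo).ravel()
    excluded = np.flatnonzero(span == 0)
    if len(excluded):
        warnings.warn(f"excluding {len(excluded)} constant row(s)")
    kept = np.flatnonzero(span > 0)
    norm = (responses[kept] - lo[kept]) / (hi[kept] - lo[kept])
    col = int(np.argmin(np.abs(lags - sort_time)))
    order = kept[np.argsort(-norm[:, col], kind="stable")]
    rank = {k: i for i, k in enumerate(kept)}
    sorted_norm = norm[[rank[k] for k in order]]
    return sorted_norm, order, excluded


def response_amplitude(trace: Trace, event_times, at_time: float = 1.0,
                       half_width: float = 0.05) -> float:
    """Mean dF/F in a small window ``at_time`` seconds after the events.

    The default reads out the response 1 s after stimulus onset.
    """
    eta = event_triggered_average(
        trace, event_times, window=(at_time - half_width,
                                    at_time + half_width))
    return float(eta.mean.mean())


# ---------------------------------------------------------------------------
# neural contrast-response fit


@dataclass
class NeuralContrastFit:
    """Fit of p + q * f(c) to per-contrast response amplitudes."""

    p: float
    q: float
    c50: float
    n: float
    converged: bool
    message: str = ""

    def predict(self, c):
        from .observer import contrast_response
        return self.p + self.q * contrast_response(c, self.c50, self.n)


def fit_neural_contrast(contrasts, amplitudes, sem=None,
                        ) -> NeuralContrastFit:
    """Least-squares fit of p + q*f(c) to contrast-response amplitudes.

    Ipsilateral conditions enter with c = 0.  For each candidate (c50, n)
    on a log-spaced grid, (p, q) is a (weighted) linear least-squares
    subproblem; the best grid point is refined with bounded Nelder-Mead.
    With fewer than 4 contrast levels, or when the fitted gain q is
    negligible, (c50, n) is unidentifiable and the fit is flagged.
    """
    from scipy import optimize

    from .observer import C50_GRID, C50_BOUNDS, N_BOUNDS, N_GRID, \
        contrast_response

    c = np.asarray(contrasts, float)
    y = np.asarray(amplitudes, float)
    if len(c) != len(y):
        raise ValueError("contrasts and amplitudes must align")
    if len(np.unique(c)) < 4:
        raise ValueError("need at least 4 distinct contrast levels")
    w = np.ones_like(y) if sem is None else 1.0 / np.clip(
        np.asarray(sem, float), 1e-12, None)

    def solve_linear(c50, n):
        f = contrast_response(c, c50, n)
        a = np.column_stack([np.ones_like(f), f]) * w[:, None]
        coef, *_ = np.linalg.lstsq(a, y * w, rcond=None)
        resid = float(((a @ coef - y * w) ** 2).sum())
        return coef, resid

    best = (np.inf, None, None)
    for c50 in C50_GRID:
        for n in N_GRID:
            coef, resid = solve_linear(c50, n)
            if resid < best[0]:
                best = (resid, coef, (c50, n))

    def fun(x):
        return solve_linear(np.exp(x[0]), np.exp(x[1]))[1]

    res = optimize.minimize(
        fun, np.log(best[2]), method="Nelder-Mead",
        bounds=[(np.log(C50_BOUNDS[0]), np.log(C50_BOUNDS[1])),
                (np.log(N_BOUNDS[0]), np.log(N_BOUNDS[1]))],
        options={"xatol": 1e-4, "fatol": 1e-12, "maxiter": 300})
    if res.fun <= best[0]:
        c50, n = np.exp(res.x)
        coef, _ = solve_linear(c50, n)
    else:
        coef, (c50, n) = best[1], best[2]
    p, q = map(float, coef)

    scale = max(1.0, float(np.abs(y).max()))
    if abs(q) < 1e-6 * scale:
        return NeuralContrastFit(p, q, float(c50), float(n), False,
                                 "flat response: c50 and n unidentifiable")
    return NeuralContrastFit(p, q, float(c50), float(n), True)
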