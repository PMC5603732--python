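"""Synthetic sessions of the steering-wheel task, with known ground truth.

Simulates the three task variants — 2AFC detection (left/right forced
choice), 2AUC detection (left/right/no-go, no-go rewarded at zero
contrast), and 2AUC contrast discrimination (two gratings, reward for the
higher contrast, pedestal = min of the two) — with choices sampled from
the probabilistic observer model.  Optogenetic inactivation sessions are
emulated by scheduling laser trials at a fixed probability and applying
known bias/sensitivity decrements on those trials, so the true change in
the decision variables at any contrast is available in closed form.

Also provides wheel-velocity and calcium-fluorescence trace fixtures with
known event times, for exercising the trace operators.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .observer import CHOICE_ORDER, ObserverParams, contrast_response
from .signals import Trace, detect_turns

__all__ = [
    "TaskConfig",
    "InactivationSpec",
    "WheelSimConfig",
    "sample_stimulus",
    "reward_rule",
    "generate_session",
    "learning_trajectory",
    "synth_wheel_trace",
    "synth_calcium",
]

#: Default per-side contrast sets (fractions).
DETECTION_CONTRASTS = (0.0, 0.06, 0.12, 0.25, 0.50)
DISCRIMINATION_PEDESTALS = (0.0, 0.10, 0.25)
DISCRIMINATION_DIFFERENCES = (0.0, 0.06, 0.12, 0.25, 0.50)

VARIANTS = ("afc2_detection", "auc2_detection", "auc2_discrimination")
LASER_REGIONS = ("Lvis", "Rvis", "Lsom", "Rsom")


@dataclass
class TaskConfig:
    """Configuration of one simulated session.

    laser_fraction is the probability that any trial carries laser
    illumination (default 0.30 when inactivating); repeat_after_error
    re-presents the previous stimulus after an incorrect response, with
    the repeat flag set so analyses can exclude those trials.
    """

    variant: str = "auc2_detection"
    contrast_set: Sequence[float] = DETECTION_CONTRASTS
    pedestal_set: Sequence[float] = DISCRIMINATION_PEDESTALS
    n_trials: int = 500
    laser_fraction: float = 0.0
    laser_regions: Sequence[str] = ("Lvis",)
    repeat_after_error: bool = False
    response_window: float = 1.5
    reward_mode: str = "water"
    session_id: str = "sim"
    day: str = "2000-01-01"

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if len(self.contrast_set) == 0:
            raise ValueError("contrast_set must be non-empty")
        cs = np.asarray(self.contrast_set, float)
        if np.any(cs < 0) or np.any(cs > 1):
            raise ValueError("contrasts must lie in [0, 1]")
        if not 0 <= self.laser_fraction <= 1:
            raise ValueError("laser_fraction must be in [0, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        unknown = set(self.laser_regions) - set(LASER_REGIONS)
        if unknown:
            raise ValueError(f"unknown laser regions: {sorted(unknown)}")


@dataclass
class InactivationSpec:
    """Ground-truth effect of laser illumination on the observer.

    Decrements are subtracted from the base parameters on laser trials.
    The induced drop in a decision variable at contrast c is then known
    exactly: delta_z_side(c) = db_side + ds_side * f(c).
    """

    ds_left: float = 0.0
    ds_right: float = 0.0
    db_left: float = 0.0
    db_right: float = 0.0

    def apply(self, params: ObserverParams) -> ObserverParams:
        return replace(params,
                       b_left=params.b_left - self.db_left,
                       b_right=params.b_right - self.db_right,
                       s_left=params.s_left - self.ds_left,
                       s_right=params.s_right - self.ds_right)

    def true_delta_z(self, params: ObserverParams, c: float = 0.5):
        """(delta_z_left, delta_z_right) at contrast c; positive = drop."""
        f = contrast_response(c, params.c50, params.n)
        return (self.db_left + self.ds_left * f,
                self.db_right + self.ds_right * f)


def contralateral_spec(region: str, delta_z_contra: float,
                       delta_z_ipsi: float, params: ObserverParams,
                       c_eval: float = 0.5) -> InactivationSpec:
    """Sensitivity-decrement spec producing given true delta-z at c_eval.

    Inactivating a left-hemisphere region degrades evidence from the
    right (contralateral) visual field, i.e. lowers z_R, and vice versa.
    """
    f = contrast_response(c_eval, params.c50, params.n)
    ds_contra = delta_z_contra / f
    ds_ipsi = delta_z_ipsi / f
    if region.startswith("L"):
        return InactivationSpec(ds_left=ds_ipsi, ds_right=ds_contra)
    return InactivationSpec(ds_left=ds_contra, ds_right=ds_ipsi)


# ---------------------------------------------------------------------------
# stimulus and reward rules


def sample_stimulus(config: TaskConfig, rng: np.random.Generator):
    """Draw (c_left, c_right) for one trial of the configured variant.

    Detection: one side gets a contrast from the contrast set, the other
    is zero; the zero-zero condition exists only in the unforced (2AUC)
    variant.  Discrimination: the pedestal (minimum contrast) is drawn
    from the pedestal set and one random side adds a contrast difference.
    """
    if config.variant == "auc2_discrimination":
        if len(config.pedestal_set) == 0:
            raise ValueError("pedestal_set must be non-empty")
        ped = float(rng.choice(np.asarray(config.pedestal_set, float)))
        diff = float(rng.choice(np.asarray(config.contrast_set, float)))
        hi = min(ped + diff, 1.0)
        if rng.random() < 0.5:
            return hi, ped
        return ped, hi
    cs = np.asarray(config.contrast_set, float)
    if config.variant == "afc2_detection":
        cs = cs[cs > 0]
        if len(cs) == 0:
            raise ValueError("2AFC detection needs nonzero contrasts")
    c = float(rng.choice(cs))
    if c == 0.0:
        return 0.0, 0.0
    if rng.random() < 0.5:
        return c, 0.0
    return 0.0, c


def reward_rule(c_left: float, c_right: float, choice: str,
                rng: np.random.Generator, variant: str = "auc2_detection"):
    """Score one response: (correct, rewarded).

    The side with the higher contrast is correct.  Equal nonzero
    contrasts: either go response is rewarded at random with probability
    one half.  A no-go is rewarded only when no grating is present on
    either side; in the forced-choice variant no-go is not a valid
    response.
    """
    if choice not in CHOICE_ORDER:
        raise ValueError(f"unknown choice {choice!r}")
    if variant == "afc2_detection" and choice == "NG":
        raise ValueError("no-go response is invalid in the 2AFC variant")
    if choice == "NG":
        correct = (c_left == 0.0 and c_right == 0.0)
        return correct, correct
    if c_left == c_right:
        if c_left == 0.0:
            # go response with no stimulus present: never rewarded
            return False, False
        rewarded = bool(rng.random() < 0.5)
        return rewarded, rewarded
    correct = (c_left > c_right) == (choice == "L")
    return correct, correct


# ---------------------------------------------------------------------------
# session generation


def learning_trajectory(n_trials: int, s_final: float, rate: float,
                        b_left: float = 0.0, b_right: float = 0.0,
                        c50: float = 0.15, n: float = 2.0) -> pd.DataFrame:
    """Per-trial observer parameters of a gradually learning subject.

    Sensitivities grow as s(t) = s_final * (1 - exp(-t/rate)) with the
    trial index t; biases and the contrast nonlinearity stay fixed.
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    t = np.arange(n_trials)
    s = s_final * (1.0 - np.exp(-t / rate))
    return pd.DataFrame({
        "b_left": b_left, "b_right": b_right,
        "s_left": s, "s_right": s, "c50": c50, "n": n,
    })


def _params_frame(params, n_trials: int) -> pd.DataFrame:
    if isinstance(params, ObserverParams):
        return pd.DataFrame({
            "b_left": params.b_left, "b_right": params.b_right,
            "s_left": params.s_left, "s_right": params.s_right,
            "c50": params.c50, "n": params.n,
        }, index=range(n_trials), dtype=float)
    frame = pd.DataFrame(params).astype(float)
    if len(frame) < n_trials:
        raise ValueError("parameter trajectory shorter than n_trials")
    return frame.iloc[:n_trials].reset_index(drop=True)


def _sample_choice_rows(cl, cr, pf, laser_region, spec_map, variant, rng):
    """Vectorized choice sampling for a block of trials."""
    n = len(cl)
    b_l = pf["b_left"].to_numpy().copy()
    b_r = pf["b_right"].to_numpy().copy()
    s_l = pf["s_left"].to_numpy().copy()
    s_r = pf["s_right"].to_numpy().copy()
    for region, spec in spec_map.items():
        m = laser_region == region
        b_l[m] -= spec.db_left
        b_r[m] -= spec.db_right
        s_l[m] -= spec.ds_left
        s_r[m] -= spec.ds_right
    c50 = pf["c50"].to_numpy()
    nn = pf["n"].to_numpy()
    f_l = np.power(cl, nn) / (np.power(c50, nn) + np.power(cl, nn))
    f_r = np.power(cr, nn) / (np.power(c50, nn) + np.power(cr, nn))
    f_l = np.where(cl == 0, 0.0, f_l)
    f_r = np.where(cr == 0, 0.0, f_r)
    z_l = b_l + s_l * f_l
    z_r = b_r + s_r * f_r
    u = rng.random(n)
    if variant == "afc2_detection":
        p_r = 1.0 / (1.0 + np.exp(-(z_r - z_l)))
        return np.where(u < p_r, "R", "L")
    m = np.maximum(0.0, np.maximum(z_l, z_r))
    e0, el, er = np.exp(-m), np.exp(z_l - m), np.exp(z_r - m)
    d = e0 + el + er
    p_l, p_ng = el / d, e0 / d
    out = np.full(n, "R", dtype=object)
    out[u < p_l + p_ng] = "NG"
    out[u < p_l] = "L"
    return out


def generate_session(config: TaskConfig, params,
                     inactivation: Mapping[str, InactivationSpec]
                     | InactivationSpec | None = None,
                     rng: np.random.Generator | int | None = None,
                     ) -> pd.DataFrame:
    """Simulate one session; returns a trial table.

    ``params`` is either a single :class:`ObserverParams` or a per-trial
    trajectory (as from :func:`learning_trajectory`).  ``inactivation``
    maps laser regions to their ground-truth effects (a bare spec applies
    to every region in ``config.laser_regions``).  The returned table has
    the canonical columns (session_id, day, trial, c_left, c_right,
    choice, correct, rewarded, laser, repeat, rt) and is bit-identical
    for a fixed rng seed.
    """
    rng = np.random.default_rng(rng)
    n = config.n_trials
    pf = _params_frame(params, n)
    if isinstance(inactivation, InactivationSpec):
        spec_map = {r: inactivation for r in config.laser_regions}
    else:
        spec_map = dict(inactivation or {})

    # stimulus, laser and response-time draws are per-trial
    stim = np.array([sample_stimulus(config, rng) for _ in range(n)])
    laser_on = rng.random(n) < config.laser_fraction
    region_draw = rng.integers(0, max(len(config.laser_regions), 1), size=n)
    laser = np.where(
        laser_on,
        np.asarray(config.laser_regions, object)[region_draw]
        if len(config.laser_regions) else "none",
        "none")

    cl, cr = stim[:, 0].copy(), stim[:, 1].copy()
    repeat = np.zeros(n, dtype=int)

    if not config.repeat_after_error:
        choice = _sample_choice_rows(cl, cr, pf, laser, spec_map,
                                     config.variant, rng)
        correct = np.empty(n, dtype=bool)
        rewarded = np.empty(n, dtype=bool)
        for i in range(n):
            correct[i], rewarded[i] = reward_rule(
                cl[i], cr[i], choice[i], rng, config.variant)
    else:
        choice = np.empty(n, dtype=object)
        correct = np.zeros(n, dtype=bool)
        rewarded = np.zeros(n, dtype=bool)
        for i in range(n):
            if i > 0 and not correct[i - 1] and repeat[i - 1] == 0:
                cl[i], cr[i] = cl[i - 1], cr[i - 1]
                repeat[i] = 1
            row = pf.iloc[[i]]
            choice[i] = _sample_choice_rows(
                cl[i:i + 1], cr[i:i + 1], row,
                laser[i:i + 1], spec_map, config.variant, rng)[0]
            correct[i], rewarded[i] = reward_rule(
                cl[i], cr[i], choice[i], rng, config.variant)

    # response latency: lognormal, faster at high contrast; no-go has none
    c_max = np.maximum(cl, cr)
    median_rt = 0.45 / (1.0 + 2.0 * c_max)
    rt = np.minimum(median_rt * np.exp(0.35 * rng.standard_normal(n)),
                    config.response_window)
    rt[choice == "NG"] = np.nan

    return pd.DataFrame({
        "session_id": config.session_id,
        "day": config.day,
        "trial": np.arange(1, n + 1),
        "c_left": cl, "c_right": cr,
        "choice": choice,
        "correct": correct.astype(int),
        "rewarded": rewarded.astype(int),
        "laser": laser,
        "repeat": repeat,
        "rt": rt,
    })


# ---------------------------------------------------------------------------
# trace fixtures


@dataclass
class WheelSimConfig:
    """Kinematics of the simulated wheel-velocity trace.

    Each go trial contributes one smooth velocity pulse inside its trial
    slot; no-go trials contribute nothing.  Ground-truth turn events are
    the Schmitt-trigger crossings of the noise-free trace at thresholds
    (truth_high, truth_low) x amplitude.
    """

    sampling_rate: float = 100.0
    trial_duration: float = 3.0
    pulse_start: float = 0.8
    pulse_duration: float = 0.6
    amplitude: float = 10.0
    noise_sd: float = 0.0
    shape: str = "hann"  # or "rect"
    truth_high: float = 0.5
    truth_low: float = 0.2


def synth_wheel_trace(trials: pd.DataFrame,
                      cfg: WheelSimConfig | None = None,
                      rng: np.random.Generator | int | None = None):
    """Wheel-velocity trace for a session, with ground-truth turn events.

    Returns (trace, events): a velocity :class:`Trace` spanning the whole
    session and the :class:`TurnEvents` of the noise-free kinematics,
    detected at thresholds ``truth_high*amplitude`` / ``truth_low*
    amplitude``.  Velocity sign follows the choice direction.
    """
    cfg = cfg or WheelSimConfig()
    rng = np.random.default_rng(rng)
    fs = cfg.sampling_rate
    slot = int(round(cfg.trial_duration * fs))
    n_samp = slot * len(trials)
    clean = np.zeros(n_samp)

    pulse_n = max(2, int(round(cfg.pulse_duration * fs)))
    if cfg.shape == "rect":
        pulse = np.ones(pulse_n)
    else:
        pulse = np.hanning(pulse_n + 2)[1:-1]
    pulse = cfg.amplitude * pulse

    for i, choice in enumerate(trials["choice"]):
        if choice == "NG":
            continue
        sign = -1.0 if choice == "L" else 1.0
        i0 = i * slot + int(round(cfg.pulse_start * fs))
        clean[i0:i0 + pulse_n] = sign * pulse[:max(0, n_samp - i0)]

    truth = detect_turns(Trace(clean, fs, kind="wheel_velocity"),
                         high_thresh=cfg.truth_high * cfg.amplitude,
                         low_thresh=cfg.truth_low * cfg.amplitude)
    noisy = clean + cfg.noise_sd * rng.standard_normal(n_samp)
    return Trace(noisy, fs, kind="wheel_velocity"), truth


def synth_calcium(event_times, duration: float, sampling_rate: float = 30.0,
                  tau_rise: float = 0.1, tau_decay: float = 0.5,
                  amplitude: float = 50.0, baseline: float = 100.0,
                  drift_amplitude: float = 0.0, drift_period: float = 120.0,
                  noise_sd: float = 0.0,
                  rng: np.random.Generator | int | None = None) -> Trace:
    """Synthetic fluorescence: transients on a drifting baseline + noise.

    Each event adds a double-exponential transient (rise tau_rise, decay
    tau_decay); the baseline drifts as a slow sinusoid.  Returns a
    fluorescence :class:`Trace` whose ground truth (event times, kernel)
    is exactly the arguments.
    """
    rng = np.random.default_rng(rng)
    fs = sampling_rate
    t = np.arange(int(round(duration * fs))) / fs
    f = np.full_like(t, float(baseline))
    if drift_amplitude:
        f += drift_amplitude * np.sin(2 * np.pi * t / drift_period)
    for t0 in np.asarray(event_times, float):
        dt = t - t0
        m = dt >= 0
        f[m] += amplitude * (np.exp(-dt[m] / tau_decay)
                             - np.exp(-dt[m] / tau_rise))
    f += noise_sd * rng.standard_normal(len(t))
    return Trace(f, fs, kind="fluorescence")
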