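"""Descriptive psychometrics: choice curves, 2AFC fits, learning curves.

Choice proportions are reported against signed contrast (left-side
stimuli at negative values — a display convention only) with exact
Clopper-Pearson 95% binomial confidence intervals.  The 2AFC psychometric
function is a cumulative Gaussian with two lapse parameters.  Learning is
tracked on easy trials (contrast >= 40%) with a centered sliding-window
binomial estimate of p(correct).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

from .observer import _drop_repeats

__all__ = [
    "PsychometricCurve",
    "PsychometricFit",
    "LearningCurve",
    "clopper_pearson",
    "signed_contrast",
    "proportion_choices",
    "fit_psychometric_2afc",
    "learning_curve",
    "trials_to_criterion",
    "daily_performance",
]

EASY_CONTRAST = 0.40


def clopper_pearson(k, n, alpha: float = 0.05):
    """Exact (Clopper-Pearson) binomial confidence interval, vectorized."""
    lo, hi = proportion_confint(k, n, alpha=alpha, method="beta")
    return np.asarray(lo, float), np.asarray(hi, float)


def signed_contrast(trials: pd.DataFrame) -> np.ndarray:
    """Signed contrast: c_right - c_left; negative means a left stimulus.

    A presentation transform for curves and fits only — the observer
    model itself always receives the non-negative pair (c_left, c_right).
    """
    return (trials["c_right"] - trials["c_left"]).to_numpy(float)


@dataclass
class PsychometricCurve:
    """Per-level choice proportions with exact 95% CIs.

    ``table`` has one row per signed-contrast level: n_trials, p_right
    with ci_low/ci_high, and (for unforced-choice data) p_left / p_nogo
    with their own intervals.  ``params`` holds a fitted psychometric
    function when one has been attached.
    """

    table: pd.DataFrame
    params: "PsychometricFit | None" = None

    @property
    def levels(self) -> np.ndarray:
        return self.table["signed_contrast"].to_numpy()


@dataclass
class PsychometricFit:
    """Cumulative-Gaussian psychometric parameters for 2AFC data.

    p_right(x) = lapse_left + (1 - lapse_left - lapse_right)
                 * Phi((x - bias_center) / slope_width)
    """

    bias_center: float
    slope_width: float
    lapse_left: float
    lapse_right: float
    log_likelihood: float
    converged: bool
    message: str = ""

    def predict(self, x):
        x = np.asarray(x, float)
        phi = stats.norm.cdf((x - self.bias_center) / self.slope_width)
        return self.lapse_left + (1 - self.lapse_left
                                  - self.lapse_right) * phi


@dataclass
class LearningCurve:
    """Sliding-window p(correct) on easy trials, with exact 95% CIs."""

    trial_index: np.ndarray
    p_correct: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    window: int
    easy_threshold: float


def proportion_choices(trials: pd.DataFrame, alpha: float = 0.05,
                       ) -> PsychometricCurve:
    """Per-signed-contrast-level choice proportions with exact CIs.

    Repeat trials are excluded.  Levels with no trials simply do not
    appear; the right-choice proportion is always reported, and for data
    containing no-go choices the left and no-go proportions are added
    (the three per-level proportions partition to one).
    """
    trials = _drop_repeats(trials)
    if len(trials) == 0:
        raise ValueError("no trials to summarize")
    x = signed_contrast(trials)
    df = trials.assign(signed_contrast=x)
    has_nogo = (df["choice"] == "NG").any()

    rows = []
    for level, grp in df.groupby("signed_contrast", sort=True):
        n = len(grp)
        k_r = int((grp["choice"] == "R").sum())
        lo, hi = clopper_pearson(k_r, n, alpha)
        row = {"signed_contrast": level, "n_trials": n,
               "p_right": k_r / n, "ci_low": float(lo), "ci_high": float(hi)}
        if has_nogo:
            for tag, col in (("L", "p_left"), ("NG", "p_nogo")):
                k = int((grp["choice"] == tag).sum())
                lo_c, hi_c = clopper_pearson(k, n, alpha)
                row[col] = k / n
                row[col + "_ci_low"] = float(lo_c)
                row[col + "_ci_high"] = float(hi_c)
        rows.append(row)
    return PsychometricCurve(pd.DataFrame(rows))


def _curve_counts(curve) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    if isinstance(curve, PsychometricCurve):
        tab = curve.table
    else:
        tab = curve
    x = tab["signed_contrast"].to_numpy(float)
    n = tab["n_trials"].to_numpy(float)
    k = np.rint(tab["p_right"].to_numpy(float) * n)
    return x, k, n


def fit_psychometric_2afc(curve, lapse_max: float = 0.3) -> PsychometricFit:
    """ML fit of the lapse-augmented cumulative Gaussian to 2AFC data.

    ``curve`` is a :class:`PsychometricCurve` (or its table) with columns
    signed_contrast, n_trials, p_right.  Lapses are bounded in
    [0, lapse_max]; parameters landing on a bound are reported with
    ``converged=False`` and a boundary message.
    """
    x, k, n = _curve_counts(curve)
    if len(x) < 4:
        raise ValueError("need at least 4 signed-contrast levels")
    span = max(x.max() - x.min(), 1e-3)
    bounds = [(x.min(), x.max()), (np.log(span * 1e-3), np.log(span * 10)),
              (0.0, lapse_max), (0.0, lapse_max)]

    def nll(theta):
        mu, log_sigma, lam_l, lam_r = theta
        p = lam_l + (1 - lam_l - lam_r) * stats.norm.cdf(
            (x - mu) / np.exp(log_sigma))
        p = np.clip(p, 1e-12, 1 - 1e-12)
        return float(-(k * np.log(p) + (n - k) * np.log1p(-p)).sum())

    best = None
    for mu0 in (x.min() / 2, 0.0, x.max() / 2):
        for sig0 in (span / 20, span / 5, span):
            res = optimize.minimize(
                nll, [mu0, np.log(sig0), 0.01, 0.01],
                method="L-BFGS-B", bounds=bounds)
            if best is None or res.fun < best.fun:
                best = res
    mu, log_sigma, lam_l, lam_r = best.x
    at_bound = (np.isclose(lam_l, lapse_max) or np.isclose(lam_r, lapse_max)
                or np.isclose(mu, bounds[0][0]) or np.isclose(mu,
                                                              bounds[0][1]))
    msg = "parameter at bound" if at_bound else ""
    return PsychometricFit(float(mu), float(np.exp(log_sigma)),
                           float(lam_l), float(lam_r), -float(best.fun),
                           bool(best.success) and not at_bound, msg)


def _easy_trials(trials: pd.DataFrame, threshold: float) -> pd.DataFrame:
    trials = _drop_repeats(trials)
    c_max = trials[["c_left", "c_right"]].max(axis=1)
    return trials.loc[c_max >= threshold]


def learning_curve(trials: pd.DataFrame, window: int = 200,
                   easy_threshold: float = EASY_CONTRAST) -> LearningCurve:
    """Centered sliding-window estimate of p(correct) on easy trials.

    The window is truncated at the edges, so the estimate there uses
    fewer trials (and wider intervals).  ``trial_index`` refers to the
    position of each easy trial within the full ordered trial stream
    (1-based), so criterion crossings can be quoted in overall trials.
    """
    trials = trials.reset_index(drop=True)
    easy = _easy_trials(trials, easy_threshold)
    if len(easy) < window / 4:
        raise ValueError(
            f"only {len(easy)} easy trials; need at least window/4 "
            f"= {window / 4:.0f}")
    correct = easy["correct"].to_numpy(int)
    pos = easy.index.to_numpy() + 1  # 1-based overall trial number
    m = len(correct)
    h = window // 2
    idx = np.arange(m)
    lo = np.maximum(idx - h, 0)
    hi = np.minimum(idx + h, m - 1)
    cs = np.concatenate([[0], np.cumsum(correct)])
    k = cs[hi + 1] - cs[lo]
    n = hi - lo + 1
    ci_lo, ci_hi = clopper_pearson(k, n)
    return LearningCurve(pos, k / n, ci_lo, ci_hi, window, easy_threshold)


def trials_to_criterion(curve: LearningCurve, level: float):
    """First overall trial at which performance exceeds ``level``.

    Requires both that the point estimate exceeds the criterion level and
    that the 95% interval excludes chance (CI lower bound above 0.5).
    Returns None when the criterion is never reached.
    """
    ok = (curve.ci_low > 0.5) & (curve.p_correct > level)
    hits = np.flatnonzero(ok)
    if len(hits) == 0:
        return None
    return int(curve.trial_index[hits[0]])


def daily_performance(trials: pd.DataFrame,
                      easy_threshold: float = EASY_CONTRAST) -> pd.DataFrame:
    """Per-day p(correct) on easy trials, with exact 95% CIs.

    Days contributing no easy trials are dropped with a warning.
    """
    easy = _easy_trials(trials, easy_threshold)
    all_days = pd.unique(trials["day"])
    missing = sorted(set(all_days) - set(easy["day"].unique()))
    if missing:
        warnings.warn(f"days with no easy trials dropped: {missing}")
    rows = []
    for day, grp in easy.groupby("day", sort=True):
        k = int(grp["correct"].sum())
        n = len(grp)
        lo, hi = clopper_pearson(k, n)
        rows.append({"day": day, "n_trials": n, "p_correct": k / n,
                     "ci_low": float(lo), "ci_high": float(hi)})
    if not rows:
        raise ValueError("no easy trials on any day")
    return pd.DataFrame(rows)
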