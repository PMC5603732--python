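"""Probabilistic observer model for steering-wheel choice tasks.

The model describes a subject choosing left, right, or no-go (withholding
movement) on each trial of a contrast detection or discrimination task.
Stimulus contrast ``c`` on each side is passed through a saturating
contrast-response function

    f(c) = c**n / (c50**n + c**n)

and combined with a bias to form one decision variable per side,

    z_L = b_L + s_L * f(c_L),    z_R = b_R + s_R * f(c_R),

which are the log odds of choosing that side over no-go:

    log(p_L / p_0) = z_L,    log(p_R / p_0) = z_R.

This is a multinomial logit with no-go as the reference category.  For a
forced-choice (2AFC) task the model reduces to a binary logistic in
``z_R - z_L``.  Fitting is a two-level scheme: for a candidate (c50, n)
the four linear parameters are a convex multinomial-regression subproblem;
(c50, n) itself is optimized over a log-spaced grid followed by bounded
derivative-free refinement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.special import expit, logsumexp

__all__ = [
    "CHOICE_ORDER",
    "StimulusCondition",
    "ObserverParams",
    "DecisionVariables",
    "ChoiceProbabilities",
    "FitResult",
    "CrossValResult",
    "contrast_response",
    "decision_variables",
    "choice_probabilities",
    "reduce_to_2afc",
    "negative_log_likelihood",
    "fit_observer",
    "fit_shared_nonlinearity",
    "crossvalidate",
]

#: Fixed category order used everywhere (and for argmax tie-breaks).
CHOICE_ORDER = ("L", "NG", "R")

#: Cap on |bias| and |sensitivity| during fitting; hitting it signals
#: separation and sets ``converged=False``.
PARAM_CAP = 30.0

#: (c50, n) search grids: log-spaced, refined locally from the best point.
C50_GRID = np.geomspace(0.02, 1.0, 12)
N_GRID = np.geomspace(0.3, 8.0, 12)
N_BOUNDS = (0.3, 8.0)
C50_BOUNDS = (0.02, 1.0)


class StimulusCondition(NamedTuple):
    """Contrast fractions on the left and right, each in [0, 1]."""

    c_left: float
    c_right: float


class DecisionVariables(NamedTuple):
    """Log odds of choosing left / right versus no-go."""

    z_left: float
    z_right: float


class ChoiceProbabilities(NamedTuple):
    """Probability simplex over (left, no-go, right)."""

    p_left: float
    p_nogo: float
    p_right: float


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of the observer model.

    b_left, b_right
        Biases toward choosing left / right relative to no-go (log odds).
    s_left, s_right
        Sensitivity weights on the contrast response of each side
        (log odds per unit f).  Unconstrained in sign: inactivation can
        drive an effective weight to or below zero.
    c50
        Semi-saturation contrast of f(c), in (0, 1].
    n
        Exponent of f(c), > 0.
    """

    b_left: float
    b_right: float
    s_left: float
    s_right: float
    c50: float
    n: float

    def __post_init__(self) -> None:
        vals = (self.b_left, self.b_right, self.s_left, self.s_right,
                self.c50, self.n)
        if not all(np.isfinite(v) for v in vals):
            raise ValueError("observer parameters must be finite")
        if self.c50 <= 0:
            raise ValueError(f"c50 must be > 0, got {self.c50}")
        if self.n <= 0:
            raise ValueError(f"n must be > 0, got {self.n}")


@dataclass
class FitResult:
    """Result of a maximum-likelihood observer fit."""

    params: ObserverParams
    log_likelihood: float
    n_trials: int
    converged: bool
    condition_predictions: pd.DataFrame
    constraint_tag: str
    message: str = ""

    def to_dict(self) -> dict:
        p = self.params
        return {
            "params": {
                "b_left": p.b_left, "b_right": p.b_right,
                "s_left": p.s_left, "s_right": p.s_right,
                "c50": p.c50, "n": p.n,
            },
            "log_likelihood": self.log_likelihood,
            "n_trials": self.n_trials,
            "converged": self.converged,
            "constraint_tag": self.constraint_tag,
            "message": self.message,
            "condition_predictions":
                self.condition_predictions.to_dict(orient="records"),
        }


@dataclass
class CrossValResult:
    """Held-out performance of one model constraint."""

    constraint_tag: str
    heldout_ll_per_trial: float
    accuracy: float
    mean_assigned_prob: float
    n_heldout: int
    fold_ll: list
    fold_accuracy: list


# ---------------------------------------------------------------------------
# model evaluation


def contrast_response(c, c50: float, n: float):
    """Saturating contrast-response function f(c) = c^n / (c50^n + c^n).

    Monotonically non-decreasing in ``c``, 0 at c = 0 and 0.5 at c = c50.
    Accepts scalars or arrays for ``c``.
    """
    c = np.asarray(c, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("contrast must be finite")
    if np.any(c < 0) or np.any(c > 1):
        raise ValueError("contrast must lie in [0, 1]")
    if not (np.isfinite(c50) and c50 > 0):
        raise ValueError(f"c50 must be a positive finite number, got {c50}")
    if not (np.isfinite(n) and n > 0):
        raise ValueError(f"n must be a positive finite number, got {n}")
    cn = np.power(c, n)
    out = cn / (c50 ** n + cn)
    return out if out.ndim else float(out)


def decision_variables(condition, params: ObserverParams):
    """Decision variables (z_left, z_right) for a stimulus condition.

    ``condition`` is a (c_left, c_right) pair; array-valued contrasts are
    broadcast elementwise.
    """
    c_left, c_right = condition
    z_l = params.b_left + params.s_left * contrast_response(
        c_left, params.c50, params.n)
    z_r = params.b_right + params.s_right * contrast_response(
        c_right, params.c50, params.n)
    if np.ndim(z_l) == 0 and np.ndim(z_r) == 0:
        return DecisionVariables(float(z_l), float(z_r))
    return DecisionVariables(z_l, z_r)


def choice_probabilities(z) -> ChoiceProbabilities:
    """Map decision variables to the (p_left, p_nogo, p_right) simplex.

    Numerically stable via max-shift normalization; safe for |z| well
    beyond 700.
    """
    z_left, z_right = np.asarray(z[0], float), np.asarray(z[1], float)
    if not (np.all(np.isfinite(z_left)) and np.all(np.isfinite(z_right))):
        raise ValueError("decision variables must be finite")
    m = np.maximum(0.0, np.maximum(z_left, z_right))
    e0 = np.exp(-m)
    el = np.exp(z_left - m)
    er = np.exp(z_right - m)
    d = e0 + el + er
    p_l, p_0, p_r = el / d, e0 / d, er / d
    if np.ndim(p_l) == 0:
        return ChoiceProbabilities(float(p_l), float(p_0), float(p_r))
    return ChoiceProbabilities(p_l, p_0, p_r)


def reduce_to_2afc(z):
    """P(choose right | a go response): logistic(z_right - z_left).

    Algebraically identical to renormalizing the trinomial probabilities
    over the two go categories.
    """
    z_left, z_right = np.asarray(z[0], float), np.asarray(z[1], float)
    out = expit(z_right - z_left)
    return float(out) if np.ndim(out) == 0 else out


# ---------------------------------------------------------------------------
# likelihood


def _validate_choices(trials: pd.DataFrame, variant: str) -> None:
    bad = set(trials["choice"].unique()) - set(CHOICE_ORDER)
    if bad:
        raise ValueError(f"unknown choice categories: {sorted(bad)}")
    if variant == "afc2" and (trials["choice"] == "NG").any():
        raise ValueError("no-go choices are invalid in strict 2AFC data")


def _aggregate_counts(trials: pd.DataFrame):
    """Collapse a trial table to per-condition choice counts.

    Returns (conditions (m, 2), counts (m, 3)) with columns of ``counts``
    in CHOICE_ORDER.  The likelihood only depends on these sufficient
    statistics, which makes fitting cost independent of trial count.
    """
    tab = (trials.groupby(["c_left", "c_right", "choice"], sort=True)
           .size().unstack("choice", fill_value=0))
    for ch in CHOICE_ORDER:
        if ch not in tab.columns:
            tab[ch] = 0
    tab = tab[list(CHOICE_ORDER)]
    conds = np.array(list(tab.index), dtype=float)
    return conds, tab.to_numpy(dtype=float)


def _nll_counts(counts, f_l, f_r, b_l, b_r, s_l, s_r):
    """Trinomial negative log-likelihood from aggregated counts."""
    z = np.column_stack([
        b_l + s_l * f_l,
        np.zeros_like(f_l),
        b_r + s_r * f_r,
    ])
    log_p = z - logsumexp(z, axis=1, keepdims=True)
    return float(-(counts * log_p).sum())


def negative_log_likelihood(trials: pd.DataFrame, params: ObserverParams,
                            variant: str = "auc2") -> float:
    """Summed -log p(observed choice) over trials, for the given params.

    For ``variant='afc2'`` the binary reduction is used (probability of
    right given go); no-go choices are then rejected.
    """
    if len(trials) == 0:
        raise ValueError("empty trial table")
    _validate_choices(trials, variant)
    conds, counts = _aggregate_counts(trials)
    f_l = contrast_response(conds[:, 0], params.c50, params.n)
    f_r = contrast_response(conds[:, 1], params.c50, params.n)
    if variant == "afc2":
        z = (params.b_right - params.b_left
             + params.s_right * f_r - params.s_left * f_l)
        # log-sigmoid for numerical stability
        log_pr = -np.logaddexp(0.0, -z)
        log_pl = -np.logaddexp(0.0, z)
        return float(-(counts[:, 2] * log_pr + counts[:, 0] * log_pl).sum())
    return _nll_counts(counts, f_l, f_r, params.b_left, params.b_right,
                       params.s_left, params.s_right)


# ---------------------------------------------------------------------------
# fitting: inner convex subproblem (linear parameters at fixed c50, n)


def _fit_linear_auc2(counts, f_l, f_r, constraint: str):
    """MLE of the linear parameters (bias/sensitivity) at fixed f values.

    Multinomial logit with no-go as reference; convex, solved with
    L-BFGS-B under the |param| <= PARAM_CAP box.
    Returns (b_l, b_r, s_l, s_r), nll, hit_cap.
    """
    n_tot = counts.sum(axis=1)

    if constraint == "equal_sensitivity":
        def objective(theta):
            b_l, b_r, s = theta
            z = np.column_stack([b_l + s * f_l, np.zeros_like(f_l),
                                 b_r + s * f_r])
            lse = logsumexp(z, axis=1)
            nll = float((n_tot * lse).sum()
                        - (counts[:, 0] * z[:, 0]).sum()
                        - (counts[:, 2] * z[:, 2]).sum())
            p = np.exp(z - lse[:, None])
            rl = n_tot * p[:, 0] - counts[:, 0]
            rr = n_tot * p[:, 2] - counts[:, 2]
            grad = np.array([rl.sum(), rr.sum(),
                             (rl * f_l).sum() + (rr * f_r).sum()])
            return nll, grad

        x0 = np.zeros(3)
        nparam = 3
    else:
        def objective(theta):
            b_l, b_r, s_l, s_r = theta
            z = np.column_stack([b_l + s_l * f_l, np.zeros_like(f_l),
                                 b_r + s_r * f_r])
            lse = logsumexp(z, axis=1)
            nll = float((n_tot * lse).sum()
                        - (counts[:, 0] * z[:, 0]).sum()
                        - (counts[:, 2] * z[:, 2]).sum())
            p = np.exp(z - lse[:, None])
            rl = n_tot * p[:, 0] - counts[:, 0]
            rr = n_tot * p[:, 2] - counts[:, 2]
            grad = np.array([rl.sum(), rr.sum(),
                             (rl * f_l).sum(), (rr * f_r).sum()])
            return nll, grad

        x0 = np.zeros(4)
        nparam = 4

    res = optimize.minimize(objective, x0, jac=True, method="L-BFGS-B",
                            bounds=[(-PARAM_CAP, PARAM_CAP)] * nparam,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-9})
    hit_cap = bool(np.any(np.abs(res.x) >= PARAM_CAP - 1e-6))
    if constraint == "equal_sensitivity":
        b_l, b_r, s = res.x
        return (b_l, b_r, s, s), float(res.fun), hit_cap
    return tuple(res.x), float(res.fun), hit_cap


def _fit_linear_afc2(counts, f_l, f_r):
    """Binary logistic fit for forced-choice data.

    Model: p_right = logistic(b + s_r f(c_R) - s_l f(c_L)).  The two
    biases are not separately identifiable without a no-go category, so
    their difference ``b`` is stored in b_right with b_left = 0.
    """
    n_l, n_r = counts[:, 0], counts[:, 2]
    n_tot = n_l + n_r

    def objective(theta):
        b, s_l, s_r = theta
        z = b + s_r * f_r - s_l * f_l
        nll = float((n_tot * np.logaddexp(0.0, z)).sum() - (n_r * z).sum())
        p = expit(z)
        r = n_tot * p - n_r
        grad = np.array([r.sum(), -(r * f_l).sum(), (r * f_r).sum()])
        return nll, grad

    res = optimize.minimize(objective, np.zeros(3), jac=True,
                            method="L-BFGS-B",
                            bounds=[(-PARAM_CAP, PARAM_CAP)] * 3,
                            options={"maxiter": 500, "ftol": 1e-12,
                                     "gtol": 1e-9})
    hit_cap = bool(np.any(np.abs(res.x) >= PARAM_CAP - 1e-6))
    b, s_l, s_r = res.x
    return (0.0, b, s_l, s_r), float(res.fun), hit_cap


def _infer_variant(trials: pd.DataFrame) -> str:
    return "auc2" if (trials["choice"] == "NG").any() else "afc2"


def _drop_repeats(trials: pd.DataFrame) -> pd.DataFrame:
    """Remove error-triggered repeat trials before any fitting."""
    if "repeat" in trials.columns:
        return trials.loc[trials["repeat"].astype(int) == 0]
    return trials


def _condition_predictions(conds, params: ObserverParams) -> pd.DataFrame:
    z = decision_variables((conds[:, 0], conds[:, 1]), params)
    p = choice_probabilities(z)
    return pd.DataFrame({
        "c_left": conds[:, 0], "c_right": conds[:, 1],
        "p_left": np.atleast_1d(p.p_left),
        "p_nogo": np.atleast_1d(p.p_nogo),
        "p_right": np.atleast_1d(p.p_right),
    })


def _grid_refine(inner, start=None):
    """Minimize ``inner(c50, n)`` by grid search + bounded Nelder-Mead.

    ``inner`` must return the NLL for a candidate nonlinearity.  Works on
    log-parameters; returns (c50, n, nll).
    """
    best = (np.inf, None)
    for c50 in C50_GRID:
        for n in N_GRID:
            val = inner(c50, n)
            if val < best[0]:
                best = (val, (c50, n))
    if start is not None:
        val = inner(*start)
        if val < best[0]:
            best = (val, start)
    c50_0, n_0 = best[1]

    def fun(x):
        return inner(np.exp(x[0]), np.exp(x[1]))

    res = optimize.minimize(
        fun, np.log([c50_0, n_0]), method="Nelder-Mead",
        bounds=[(np.log(C50_BOUNDS[0]), np.log(C50_BOUNDS[1])),
                (np.log(N_BOUNDS[0]), np.log(N_BOUNDS[1]))],
        options={"xatol": 1e-4, "fatol": 1e-8, "maxiter": 200})
    if res.fun <= best[0]:
        c50, n = np.exp(res.x)
        return float(c50), float(n), float(res.fun)
    return float(c50_0), float(n_0), float(best[0])


def fit_observer(trials: pd.DataFrame, constraint: str = "full",
                 variant: str | None = None) -> FitResult:
    """Maximum-likelihood fit of the observer model to a trial table.

    Parameters
    ----------
    trials
        Trial table with columns c_left, c_right, choice (and optionally
        repeat, which is honoured by exclusion).
    constraint
        'full' (4 linear parameters), 'equal_sensitivity' (s_L = s_R).
    variant
        'auc2', 'afc2', or None to infer from the presence of no-go
        choices.

    Returns a :class:`FitResult`; non-identifiable data (all choices in
    one category) yield a boundary result with ``converged=False``.
    """
    trials = _drop_repeats(trials)
    if len(trials) == 0:
        raise ValueError("no trials left after excluding repeats")
    if variant is None:
        variant = _infer_variant(trials)
    _validate_choices(trials, variant)
    conds, counts = _aggregate_counts(trials)
    n_trials = int(counts.sum())

    n_categories = int((counts.sum(axis=0) > 0).sum())
    if n_categories < 2:
        params = ObserverParams(0.0, 0.0, 0.0, 0.0, 0.5, 2.0)
        nll = negative_log_likelihood(trials, params, variant)
        return FitResult(params, -nll, n_trials, False,
                         _condition_predictions(conds, params), constraint,
                         "non-identifiable: all observed choices in one "
                         "category")

    cap_hit = {}

    def inner(c50, n):
        f_l = contrast_response(conds[:, 0], c50, n)
        f_r = contrast_response(conds[:, 1], c50, n)
        if variant == "afc2":
            lin, nll, hit = _fit_linear_afc2(counts, f_l, f_r)
        else:
            lin, nll, hit = _fit_linear_auc2(counts, f_l, f_r, constraint)
        cap_hit[(c50, n)] = (lin, hit)
        return nll

    c50, n, nll = _grid_refine(inner)
    lin, hit = cap_hit[(c50, n)] if (c50, n) in cap_hit else (None, None)
    if lin is None:
        inner(c50, n)
        lin, hit = cap_hit[(c50, n)]
    b_l, b_r, s_l, s_r = lin
    params = ObserverParams(b_l, b_r, s_l, s_r, c50, n)
    msg = "separation: parameter cap reached" if hit else ""
    return FitResult(params, -nll, n_trials, not hit,
                     _condition_predictions(conds, params), constraint, msg)


def fit_shared_nonlinearity(groups: Mapping[str, pd.DataFrame],
                            constraint: str = "full",
                            variant: str | None = None,
                            ) -> dict[str, FitResult]:
    """Fit several trial-table groups with one shared (c50, n).

    The nonlinearity is optimized on the pooled likelihood of all groups
    (e.g. control + laser sessions); biases and sensitivities are fit per
    group.  Returns one FitResult per group, all sharing (c50, n).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups to share a nonlinearity")
    prepared = {}
    for tag, trials in groups.items():
        trials = _drop_repeats(trials)
        if len(trials) == 0:
            raise ValueError(f"group {tag!r} is empty")
        v = variant or _infer_variant(trials)
        _validate_choices(trials, v)
        conds, counts = _aggregate_counts(trials)
        if int((counts.sum(axis=0) > 0).sum()) < 2:
            raise ValueError(f"group {tag!r} has all choices in one category")
        prepared[tag] = (conds, counts, v)

    def inner(c50, n):
        total = 0.0
        for conds, counts, v in prepared.values():
            f_l = contrast_response(conds[:, 0], c50, n)
            f_r = contrast_response(conds[:, 1], c50, n)
            if v == "afc2":
                _, nll, _ = _fit_linear_afc2(counts, f_l, f_r)
            else:
                _, nll, _ = _fit_linear_auc2(counts, f_l, f_r, constraint)
            total += nll
        return total

    c50, n, _ = _grid_refine(inner)

    out = {}
    for tag, (conds, counts, v) in prepared.items():
        f_l = contrast_response(conds[:, 0], c50, n)
        f_r = contrast_response(conds[:, 1], c50, n)
        if v == "afc2":
            lin, nll, hit = _fit_linear_afc2(counts, f_l, f_r)
        else:
            lin, nll, hit = _fit_linear_auc2(counts, f_l, f_r, constraint)
        params = ObserverParams(*lin, c50, n)
        out[tag] = FitResult(params, -nll, int(counts.sum()), not hit,
                             _condition_predictions(conds, params),
                             constraint,
                             "separation: parameter cap reached" if hit
                             else "")
    return out


# ---------------------------------------------------------------------------
# cross-validation


def _heldout_metrics(test: pd.DataFrame, params: ObserverParams,
                     variant: str):
    """Per-trial held-out log-lik, argmax hits and assigned probabilities."""
    z = decision_variables(
        (test["c_left"].to_numpy(), test["c_right"].to_numpy()), params)
    if variant == "afc2":
        p_r = reduce_to_2afc(z)
        probs = np.column_stack([1.0 - p_r, np.zeros(len(test)), p_r])
    else:
        p = choice_probabilities(z)
        probs = np.column_stack([p.p_left, p.p_nogo, p.p_right])
    idx = np.array([CHOICE_ORDER.index(c) for c in test["choice"]])
    assigned = probs[np.arange(len(test)), idx]
    ll = np.log(np.clip(assigned, 1e-300, None))
    # np.argmax returns the first maximum -> ties break in CHOICE_ORDER
    hits = probs.argmax(axis=1) == idx
    return ll, hits, assigned


def crossvalidate(trials: pd.DataFrame,
                  constraints: Sequence[str] = ("full", "equal_sensitivity"),
                  k: int = 10, seed: int = 0,
                  variant: str | None = None) -> dict[str, CrossValResult]:
    """Stratified k-fold cross-validation of observer-model constraints.

    Folds are stratified by stimulus condition so every fold sees the
    full psychometric range.  Reports, per constraint, the mean held-out
    log-likelihood per trial, the argmax choice-prediction accuracy
    (fraction of held-out trials whose observed choice has the highest
    predicted probability), and the mean probability assigned to the
    observed choices.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    if k < 2:
        raise ValueError("k must be >= 2")
    trials = _drop_repeats(trials).reset_index(drop=True)
    if variant is None:
        variant = _infer_variant(trials)
    _validate_choices(trials, variant)
    labels = (trials["c_left"].astype(str) + "/"
              + trials["c_right"].astype(str))
    min_per_cond = labels.value_counts().min()
    if k > min_per_cond:
        warnings.warn("fewer trials per condition than folds; falling back "
                      "to unstratified folds")
        splitter = KFold(n_splits=min(k, len(trials)), shuffle=True,
                         random_state=seed)
        splits = list(splitter.split(trials))
    else:
        splitter = StratifiedKFold(n_splits=k, shuffle=True,
                                   random_state=seed)
        splits = list(splitter.split(trials, labels))

    out = {}
    for constraint in constraints:
        lls, hit_chunks, prob_chunks = [], [], []
        fold_ll, fold_acc = [], []
        for train_idx, test_idx in splits:
            train = trials.iloc[train_idx]
            test = trials.iloc[test_idx]
            if train["choice"].nunique() < 2:
                warnings.warn("skipping fold whose training split has a "
                              "single choice category")
                continue
            fit = fit_observer(train, constraint=constraint, variant=variant)
            ll, hits, assigned = _heldout_metrics(test, fit.params, variant)
            lls.append(ll)
            hit_chunks.append(hits)
            prob_chunks.append(assigned)
            fold_ll.append(float(ll.mean()))
            fold_acc.append(float(hits.mean()))
        if not lls:
            raise ValueError("no usable folds")
        ll_all = np.concatenate(lls)
        hits_all = np.concatenate(hit_chunks)
        probs_all = np.concatenate(prob_chunks)
        out[constraint] = CrossValResult(
            constraint_tag=constraint,
            heldout_ll_per_trial=float(ll_all.mean()),
            accuracy=float(hits_all.mean()),
            mean_assigned_prob=float(probs_all.mean()),
            n_heldout=int(len(ll_all)),
            fold_ll=fold_ll,
            fold_accuracy=fold_acc,
        )
    return out
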