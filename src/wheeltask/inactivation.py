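"""Quantifying optogenetic inactivation in decision-variable space.

The effect of silencing a cortical region during the task is summarized
as the drop it causes in the two decision variables of the observer
model, evaluated at 50% contrast: control and laser trials are fit with
a shared contrast nonlinearity (c50, n), and

    delta_z_side = z_side(0.5 | control) - z_side(0.5 | laser).

Positive values mean the laser decreased that decision variable.  The
session is the unit of replication: contralateral-vs-ipsilateral effects
within a region are compared with a paired one-sided t test, and effect
sizes between regions with an exact Wilcoxon rank-sum test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .observer import FitResult, decision_variables

__all__ = [
    "InactivationEffect",
    "inactivation_deltas",
    "paired_contra_ipsi_test",
    "region_comparison_test",
]

REGIONS = ("Lvis", "Rvis", "Lsom", "Rsom")


@dataclass
class InactivationEffect:
    """Per-session drop in the decision variables at 50% contrast.

    Positive delta = the laser decreased that decision variable.
    """

    session_id: str
    region: str
    delta_z_left: float
    delta_z_right: float

    def contra_ipsi(self) -> tuple[float, float]:
        """(contralateral, ipsilateral) delta for this region.

        A left-hemisphere region processes the right visual field, so its
        contralateral effect is the drop in z_right, and vice versa.
        """
        if self.region.startswith("L"):
            return self.delta_z_right, self.delta_z_left
        return self.delta_z_left, self.delta_z_right


def inactivation_deltas(control_fit: FitResult, laser_fit: FitResult,
                        c_eval: float = 0.5, session_id: str = "",
                        region: str = "Lvis") -> InactivationEffect:
    """Drop in (z_left, z_right) at contrast ``c_eval`` due to the laser.

    Both fits must share the contrast nonlinearity (c50, n), as produced
    by :func:`wheeltask.observer.fit_shared_nonlinearity`; otherwise the
    two decision variables live on different contrast scales and the
    difference is not interpretable.
    """
    pc, pl = control_fit.params, laser_fit.params
    if not (math.isclose(pc.c50, pl.c50, rel_tol=1e-9)
            and math.isclose(pc.n, pl.n, rel_tol=1e-9)):
        raise ValueError("control and laser fits must share (c50, n); "
                         "use fit_shared_nonlinearity")
    z_c = decision_variables((c_eval, c_eval), pc)
    z_l = decision_variables((c_eval, c_eval), pl)
    return InactivationEffect(session_id, region,
                              z_c.z_left - z_l.z_left,
                              z_c.z_right - z_l.z_right)


@dataclass
class PairedTestResult:
    p_value: float
    t_statistic: float
    contra_mean: float
    contra_sem: float
    ipsi_mean: float
    ipsi_sem: float
    n_sessions: int
    degenerate: bool = False


def paired_contra_ipsi_test(effects: list[InactivationEffect],
                            ) -> PairedTestResult:
    """Paired one-sided t test: contralateral drop > ipsilateral drop.

    All effects must come from the same region (sessions are the pairs).
    Zero variance of the paired differences is degenerate: the p-value is
    0 for a uniformly positive gap, 1 for a negative one, and 0.5 when
    the two sides are identical.
    """
    if len(effects) < 3:
        raise ValueError("need at least 3 sessions")
    regions = {e.region for e in effects}
    if len(regions) > 1:
        raise ValueError(f"effects mix regions: {sorted(regions)}")
    contra = np.array([e.contra_ipsi()[0] for e in effects])
    ipsi = np.array([e.contra_ipsi()[1] for e in effects])
    diff = contra - ipsi
    n = len(diff)

    def sem(x):
        return float(x.std(ddof=1) / np.sqrt(len(x)))

    if np.allclose(diff.std(ddof=1), 0.0):
        gap = float(diff.mean())
        p = 0.5 if np.isclose(gap, 0.0) else (0.0 if gap > 0 else 1.0)
        return PairedTestResult(p, np.inf if gap > 0 else -np.inf,
                                float(contra.mean()), sem(contra),
                                float(ipsi.mean()), sem(ipsi), n,
                                degenerate=True)
    res = stats.ttest_rel(contra, ipsi, alternative="greater")
    return PairedTestResult(float(res.pvalue), float(res.statistic),
                            float(contra.mean()), sem(contra),
                            float(ipsi.mean()), sem(ipsi), n)


@dataclass
class RankSumResult:
    p_value: float
    statistic: float
    n_a: int
    n_b: int
    method: str


def region_comparison_test(effects_a: list[InactivationEffect],
                           effects_b: list[InactivationEffect],
                           side: str = "contra") -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test of effect sizes between regions.

    ``side`` selects which delta to compare: 'contra'/'ipsi' (relative to
    each region's hemisphere) or 'left'/'right' (absolute).  The exact
    null distribution is used for groups of up to 10 sessions (ties are
    then counted without correction); larger groups use the normal
    approximation with tie correction.
    """
    if len(effects_a) < 3 or len(effects_b) < 3:
        raise ValueError("need at least 3 sessions per region")

    def pick(e: InactivationEffect) -> float:
        if side == "contra":
            return e.contra_ipsi()[0]
        if side == "ipsi":
            return e.contra_ipsi()[1]
        if side == "left":
            return e.delta_z_left
        if side == "right":
            return e.delta_z_right
        raise ValueError(f"unknown side {side!r}")

    a = np.array([pick(e) for e in effects_a])
    b = np.array([pick(e) for e in effects_b])
    method = "exact" if max(len(a), len(b)) <= 10 else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return RankSumResult(float(min(res.pvalue, 1.0)), float(res.statistic),
                         len(a), len(b), method)
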