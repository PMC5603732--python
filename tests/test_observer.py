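"""Observer model: evaluation, likelihood, fitting, cross-validation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from wheeltask import (ObserverParams, TaskConfig, choice_probabilities,
                       contrast_response, crossvalidate, decision_variables,
                       fit_observer, fit_shared_nonlinearity,
                       generate_session, negative_log_likelihood,
                       reduce_to_2afc)
from wheeltask.observer import CHOICE_ORDER

from conftest import CONTRASTS_11


class TestContrastResponse:
    @pytest.mark.parametrize("c,c50,n,expected", [
        (0.0, 0.3, 2.0, 0.0),            # zero numerator
        (0.25, 0.25, 3.7, 0.5),          # c = c50 halves the response
        (0.5, 0.25, 2.0, 0.8),           # 0.25 / (0.0625 + 0.25)
        (1.0, 1.0, 1.0, 0.5),
    ])
    def test_known_values(self, c, c50, n, expected):
        assert contrast_response(c, c50, n) == pytest.approx(expected)

    def test_monotone_in_contrast(self):
        c = np.linspace(0, 1, 50)
        f = contrast_response(c, 0.1, 1.7)
        assert np.all(np.diff(f) >= 0)
        assert np.all((f >= 0) & (f < 1))

    @pytest.mark.parametrize("bad", [
        {"c": -0.1}, {"c": 1.5}, {"c": np.nan},
        {"c50": 0.0}, {"c50": -1.0}, {"n": 0.0}, {"n": np.inf},
    ])
    def test_domain_errors(self, bad):
        kw = {"c": 0.5, "c50": 0.3, "n": 2.0, **bad}
        with pytest.raises(ValueError):
            contrast_response(**kw)


class TestDecisionVariables:
    def test_zero_contrast_gives_biases(self):
        p = ObserverParams(-0.7, 0.4, 5.0, 6.0, 0.2, 2.0)
        z = decision_variables((0.0, 0.0), p)
        assert z == (-0.7, 0.4)

    def test_at_c50(self):
        p = ObserverParams(-1.0, 0.0, 4.0, 4.0, 0.2, 3.0)
        z = decision_variables((0.2, 0.0), p)
        assert z.z_left == pytest.approx(-1.0 + 4.0 * 0.5)

    def test_hand_evaluated(self):
        p = ObserverParams(0.0, 0.0, 2.0, 2.0, 0.25, 2.0)
        z = decision_variables((0.5, 0.0), p)
        assert z.z_left == pytest.approx(1.6)
        assert z.z_right == pytest.approx(0.0)


class TestChoiceProbabilities:
    def test_symmetric(self):
        p = choice_probabilities((0.0, 0.0))
        assert p == pytest.approx((1 / 3, 1 / 3, 1 / 3))

    def test_binary_logistic_limit(self):
        p = choice_probabilities((np.log(2.0), -40.0))
        assert p.p_left == pytest.approx(2 / 3, abs=1e-9)
        assert p.p_nogo == pytest.approx(1 / 3, abs=1e-9)
        assert p.p_right == pytest.approx(0.0, abs=1e-9)

    def test_hand_evaluated(self):
        p = choice_probabilities((1.0, -1.0))
        assert p.p_left == pytest.approx(0.6652, abs=1e-4)
        assert p.p_nogo == pytest.approx(0.2447, abs=1e-4)
        assert p.p_right == pytest.approx(0.0900, abs=1e-4)

    @given(z_l=st.floats(-700, 700), z_r=st.floats(-700, 700))
    @settings(max_examples=200, deadline=None)
    def test_simplex_property(self, z_l, z_r):
        p = choice_probabilities((z_l, z_r))
        assert abs(p.p_left + p.p_nogo + p.p_right - 1.0) < 1e-12
        assert min(p) >= 0.0

    @given(b_r=st.floats(-3, 3), s_r=st.floats(0.1, 10),
           c50=st.floats(0.05, 1.0), n=st.floats(0.5, 5))
    @settings(max_examples=50, deadline=None)
    def test_p_right_monotone_in_contrast(self, b_r, s_r, c50, n):
        """With positive sensitivity, more contrast means more right."""
        params = ObserverParams(0.0, b_r, 1.0, s_r, c50, n)
        c = np.linspace(0, 1, 21)
        z = decision_variables((np.zeros_like(c), c), params)
        p = choice_probabilities(z)
        assert np.all(np.diff(p.p_right) >= -1e-12)


class TestReduceTo2afc:
    def test_symmetry(self):
        assert reduce_to_2afc((1.3, 1.3)) == pytest.approx(0.5)

    def test_hand_evaluated(self):
        assert reduce_to_2afc((0.0, 1.0)) == pytest.approx(
            np.e / (1 + np.e), abs=1e-4)

    @given(z_l=st.floats(-30, 30), z_r=st.floats(-30, 30))
    @settings(max_examples=100, deadline=None)
    def test_equals_conditional_renormalization(self, z_l, z_r):
        p = choice_probabilities((z_l, z_r))
        expected = p.p_right / (p.p_left + p.p_right)
        assert reduce_to_2afc((z_l, z_r)) == pytest.approx(
            expected, abs=1e-12)


def brute_force_nll(trials, params):
    """Independent per-trial oracle for the trinomial likelihood."""
    total = 0.0
    for _, row in trials.iterrows():
        z = decision_variables((row.c_left, row.c_right), params)
        d = 1.0 + np.exp(z.z_left) + np.exp(z.z_right)
        p = {"L": np.exp(z.z_left) / d, "NG": 1.0 / d,
             "R": np.exp(z.z_right) / d}[row.choice]
        total -= np.log(p)
    return total


class TestNegativeLogLikelihood:
    def test_single_trial_binary_limit(self):
        trials = _table([(0.0, 0.0, "L")])
        params = ObserverParams(0.0, -30.0, 1.0, 1.0, 0.2, 2.0)
        assert negative_log_likelihood(trials, params) == pytest.approx(
            np.log(2), abs=1e-9)

    def test_single_nogo_trial(self):
        trials = _table([(0.0, 0.0, "NG")])
        params = ObserverParams(0.0, 0.0, 1.0, 1.0, 0.2, 2.0)
        assert negative_log_likelihood(trials, params) == pytest.approx(
            np.log(3))

    def test_matches_brute_force_oracle(self, rng):
        conds = [(0.0, 0.0), (0.5, 0.0), (0.0, 0.25), (0.12, 0.0)]
        rows = [(cl, cr, rng.choice(list(CHOICE_ORDER)))
                for cl, cr in conds for _ in range(5)]
        trials = _table(rows)
        params = ObserverParams(-0.4, 0.6, 3.0, 5.0, 0.11, 1.6)
        assert negative_log_likelihood(trials, params) == pytest.approx(
            brute_force_nll(trials, params), abs=1e-10)

    def test_additive_over_subsets(self, auc2_session, default_params):
        a, b = auc2_session.iloc[:800], auc2_session.iloc[800:]
        whole = negative_log_likelihood(auc2_session, default_params)
        assert whole == pytest.approx(
            negative_log_likelihood(a, default_params)
            + negative_log_likelihood(b, default_params), abs=1e-8)

    def test_nogo_rejected_in_2afc(self):
        trials = _table([(0.5, 0.0, "NG")])
        params = ObserverParams(0.0, 0.0, 1.0, 1.0, 0.2, 2.0)
        with pytest.raises(ValueError):
            negative_log_likelihood(trials, params, variant="afc2")


def _table(rows):
    return pd.DataFrame(
        [{"c_left": cl, "c_right": cr, "choice": ch, "repeat": 0}
         for cl, cr, ch in rows])


class TestFitObserver:
    def test_mle_dominance(self, auc2_session, default_params):
        """The fitted likelihood can never fall below the truth's."""
        fit = fit_observer(auc2_session)
        gen_ll = -negative_log_likelihood(auc2_session, default_params)
        assert fit.log_likelihood >= gen_ll - 1e-6
        assert fit.log_likelihood <= 0
        assert fit.converged

    def test_parameter_recovery(self, default_params):
        cfg = TaskConfig(variant="auc2_detection", n_trials=10_000,
                         contrast_set=CONTRASTS_11)
        trials = generate_session(cfg, default_params, rng=3)
        p = fit_observer(trials).params
        assert p.b_left == pytest.approx(default_params.b_left, abs=0.2)
        assert p.b_right == pytest.approx(default_params.b_right, abs=0.2)
        assert p.s_left == pytest.approx(default_params.s_left, rel=0.10)
        assert p.s_right == pytest.approx(default_params.s_right, rel=0.10)

    def test_all_nogo_flagged_non_identifiable(self):
        trials = _table([(0.0, 0.0, "NG")] * 20)
        fit = fit_observer(trials)
        assert not fit.converged
        assert "non-identifiable" in fit.message

    def test_predictions_on_simplex(self, auc2_session):
        pred = fit_observer(auc2_session).condition_predictions
        total = pred[["p_left", "p_nogo", "p_right"]].sum(axis=1)
        assert np.allclose(total, 1.0, atol=1e-12)

    def test_equal_sensitivity_constraint(self):
        params = ObserverParams(0.2, 0.2, 5.0, 5.0, 0.15, 2.0)
        cfg = TaskConfig(variant="auc2_detection", n_trials=4000,
                         contrast_set=CONTRASTS_11)
        trials = generate_session(cfg, params, rng=5)
        fit = fit_observer(trials, constraint="equal_sensitivity")
        assert fit.params.s_left == fit.params.s_right
        full = fit_observer(trials, constraint="full")
        # nested models: the full fit is at least as good in-sample
        assert full.log_likelihood >= fit.log_likelihood - 1e-6

    def test_2afc_reduction_fit(self, afc2_session):
        fit = fit_observer(afc2_session, variant="afc2")
        assert fit.converged
        # binary reduction stores the bias difference in b_right
        assert fit.params.b_left == 0.0
        assert fit.params.s_right > 0

    def test_repeat_trials_excluded(self, auc2_session):
        flagged = auc2_session.copy()
        flagged.loc[flagged.index[:500], "repeat"] = 1
        fit_all = fit_observer(auc2_session)
        fit_flagged = fit_observer(flagged)
        assert fit_flagged.n_trials == len(auc2_session) - 500
        assert fit_flagged.log_likelihood != fit_all.log_likelihood


class TestFitSharedNonlinearity:
    def test_shared_nonlinearity_and_per_group_params(self, default_params):
        cfg = TaskConfig(variant="auc2_detection", n_trials=4000,
                         contrast_set=CONTRASTS_11)
        weak = ObserverParams(-0.5, 0.3, 2.5, 3.0, 0.15, 2.0)
        groups = {"a": generate_session(cfg, default_params, rng=1),
                  "b": generate_session(cfg, weak, rng=2)}
        fits = fit_shared_nonlinearity(groups)
        assert fits["a"].params.c50 == fits["b"].params.c50
        assert fits["a"].params.n == fits["b"].params.n
        assert fits["a"].params.s_left > fits["b"].params.s_left
        assert fits["a"].params.s_right > fits["b"].params.s_right

    def test_identical_groups_agree(self, auc2_session):
        fits = fit_shared_nonlinearity({"x": auc2_session,
                                        "y": auc2_session.copy()})
        px, py = fits["x"].params, fits["y"].params
        assert px.s_left == pytest.approx(py.s_left, abs=1e-6)
        assert px.b_right == pytest.approx(py.b_right, abs=1e-6)

    def test_empty_group_rejected(self, auc2_session):
        with pytest.raises(ValueError):
            fit_shared_nonlinearity(
                {"a": auc2_session, "b": auc2_session.iloc[:0]})

    def test_single_group_rejected(self, auc2_session):
        with pytest.raises(ValueError):
            fit_shared_nonlinearity({"a": auc2_session})


class TestCrossvalidate:
    def test_equal_sensitivity_wins_on_symmetric_truth(self):
        """Fewer parameters, same truth: s_L=s_R generalizes at least
        as well on data generated with equal sensitivities."""
        params = ObserverParams(0.1, 0.1, 5.0, 5.0, 0.15, 2.0)
        cfg = TaskConfig(variant="auc2_detection", n_trials=1500,
                         contrast_set=CONTRASTS_11)
        wins = 0
        for seed in range(3):
            trials = generate_session(cfg, params, rng=seed)
            cv = crossvalidate(trials, k=5, seed=seed)
            if (cv["equal_sensitivity"].heldout_ll_per_trial
                    >= cv["full"].heldout_ll_per_trial - 5e-3):
                wins += 1
        assert wins >= 2

    def test_leave_one_out_runs(self):
        params = ObserverParams(0.0, 0.0, 4.0, 4.0, 0.15, 2.0)
        cfg = TaskConfig(variant="auc2_detection", n_trials=50)
        trials = generate_session(cfg, params, rng=0)
        with pytest.warns(UserWarning):
            cv = crossvalidate(trials, constraints=("full",), k=50, seed=0)
        assert cv["full"].n_heldout <= 50

    def test_reports_both_metrics(self, auc2_session):
        cv = crossvalidate(auc2_session, constraints=("full",), k=4, seed=1)
        r = cv["full"]
        assert 0 <= r.accuracy <= 1
        assert 0 <= r.mean_assigned_prob <= 1
        assert r.heldout_ll_per_trial < 0
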