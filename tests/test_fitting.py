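"""Replay likelihood, the three-route equivalence, MLE fitting and AIC."""

import math

import numpy as np
import pytest

import prtrace as pt
from .oracle import oracle_replay, random_labels, random_params

KINDS = ["simpleq", "asymmetry", "perseverance", "nolearn"]


def _to_paramset(d, kind):
    common = dict(beta=d["beta"], q0=(d["q0_ALP"], d["q0_MNP"], d["q0_ILP"]))
    if kind == "simpleq":
        return pt.ParamSet(alpha=d["alpha"], **common)
    if kind == "asymmetry":
        return pt.ParamSet(alpha_pos=d["alpha_pos"], alpha_neg=d["alpha_neg"], **common)
    trace = dict(tau=d["tau"], phi=(d["phi_ALP"], d["phi_MNP"], d["phi_ILP"]))
    if kind == "nolearn":
        return pt.ParamSet(**common, **trace)
    return pt.ParamSet(alpha=d["alpha"], **common, **trace)


def _log_from_labels(labels):
    codes = [{"ALP": 0, "MNP": 1, "ILP": 2, "REWARD": 3}[lab] for lab in labels]
    return pt.EventLog(np.arange(len(codes), dtype=float), np.array(codes))


class TestReplayLoglik:
    def test_uniform_policy_single_choice(self):
        log = _log_from_labels(["ALP"])
        params = pt.ParamSet(alpha=0.1, beta=0.0, q0=(0.3, -0.2, 0.9))
        res = pt.replay_loglik(log, params, "simpleq")
        assert res.loglik == pytest.approx(math.log(1 / 3), abs=1e-12)
        assert res.n_choice_events == 1

    def test_rewards_add_no_likelihood_terms(self):
        params = pt.ParamSet(alpha=0.1, beta=1.0, q0=(0.3, 0.2, 0.1))
        ll_a = pt.replay_loglik(_log_from_labels(["ALP"]), params, "simpleq").loglik
        res_b = pt.replay_loglik(_log_from_labels(["ALP", "REWARD"]), params, "simpleq")
        assert res_b.loglik == ll_a
        assert res_b.n_choice_events == 1
        assert np.isnan(res_b.p_chosen[1])
        # the forced magazine update with r=1 moved only q_MNP
        assert res_b.q[1, 1] > 0.2 and res_b.q[1, 0] == res_b.q[0, 0]

    def test_matches_brute_force_oracle_on_many_random_logs(self):
        """Three-route agreement: compiled kernel vs naive dict-based
        re-implementation, across all four model variants, 1e-10."""
        rng = np.random.default_rng(42)
        for i in range(120):
            kind = KINDS[i % 4]
            pd = random_params(rng, kind)
            labels = random_labels(rng, int(rng.integers(5, 60)))
            exp_ll, exp_n, exp_rpes, exp_q, _ = oracle_replay(labels, pd, kind)
            res = pt.replay_loglik(_log_from_labels(labels), _to_paramset(pd, kind), kind)
            assert res.loglik == pytest.approx(exp_ll, abs=1e-10)
            assert res.n_choice_events == exp_n
            assert np.allclose(res.rpe, exp_rpes, atol=1e-10)
            assert res.q[-1, 0] == pytest.approx(exp_q[-1]["ALP"], abs=1e-10)

    def test_matches_python_reference_path(self, short_run, ref_params):
        """The compiled kernel and the models.update/action_probabilities
        reference implementation walk the same trajectory."""
        kind = pt.ModelKind.PERSEVERANCE
        res = pt.replay_loglik(short_run.log, ref_params, kind)
        state = pt.init_state(ref_params, kind)
        ll = 0.0
        for i, code in enumerate(short_run.log.codes):
            if code == 3:
                state, _ = pt.update(state, pt.Action.MNP, pt.Outcome(1), ref_params, kind)
            else:
                p = pt.action_probabilities(state, ref_params, kind)
                ll += math.log(p[code])
                state, _ = pt.update(state, pt.Action(code), pt.Outcome(0), ref_params, kind)
            assert np.allclose(res.q[i], state.q, atol=1e-12)
        assert res.loglik == pytest.approx(ll, abs=1e-10)

    def test_nesting_equalities_on_one_log(self, short_run):
        q0 = (0.5, 0.3, 0.1)
        base = pt.ParamSet(alpha=0.02, beta=8.0, q0=q0)
        pers0 = pt.ParamSet(alpha=0.02, beta=8.0, q0=q0, tau=0.6, phi=(0.0, 0.0, 0.0))
        asym = pt.ParamSet(alpha_pos=0.02, alpha_neg=0.02, beta=8.0, q0=q0)
        ll = pt.replay_loglik(short_run.log, base, "simpleq").loglik
        assert pt.replay_loglik(short_run.log, pers0, "perseverance").loglik == pytest.approx(ll, abs=1e-12)
        assert pt.replay_loglik(short_run.log, asym, "asymmetry").loglik == pytest.approx(ll, abs=1e-12)
        pers_frozen = pt.ParamSet(alpha=0.0, beta=8.0, q0=q0, tau=0.6, phi=(1.0, -9.0, 2.0))
        nolearn = pt.ParamSet(beta=8.0, q0=q0, tau=0.6, phi=(1.0, -9.0, 2.0))
        assert (pt.replay_loglik(short_run.log, pers_frozen, "perseverance").loglik
                == pytest.approx(pt.replay_loglik(short_run.log, nolearn, "nolearn").loglik,
                                 abs=1e-12))

    def test_loglik_is_nonpositive_and_bounded_by_worst_choice(self, short_run, ref_params):
        res = pt.replay_loglik(short_run.log, ref_params, "perseverance")
        assert res.loglik <= 0.0
        pmin = np.nanmin(res.p_chosen)
        assert res.loglik >= res.n_choice_events * math.log(pmin)

    def test_empty_or_choiceless_log_rejected(self):
        with pytest.raises(ValueError):
            pt.replay_loglik(_log_from_labels(["REWARD"]),
                             pt.ParamSet(alpha=0.1, beta=1.0, q0=(0, 0, 0)), "simpleq")


class TestAic:
    def test_identity(self):
        assert pt.aic(-100.0, 5) == 210.0
        assert pt.aic(0.0, 8) == 16.0

    def test_literal_free_parameter_counts(self):
        assert pt.N_FREE_PARAMS[pt.ModelKind.SIMPLEQ] == 5
        assert pt.N_FREE_PARAMS[pt.ModelKind.ASYMMETRY] == 6
        assert pt.N_FREE_PARAMS[pt.ModelKind.PERSEVERANCE] == 9
        assert pt.N_FREE_PARAMS[pt.ModelKind.NOLEARN] == 8

    def test_alternative_accounting_for_trace_models(self):
        assert pt.n_free_params(pt.ModelKind.PERSEVERANCE, paper_param_counts=True) == 8
        assert pt.n_free_params(pt.ModelKind.NOLEARN, paper_param_counts=True) == 7

    def test_requires_at_least_one_parameter(self):
        with pytest.raises(ValueError):
            pt.aic(-1.0, 0)


class TestFit:
    def test_same_seed_is_bit_identical(self, short_run):
        cfg = pt.FitConfig(n_starts=3, seed=9)
        a = pt.fit(short_run.log, "simpleq", cfg)
        b = pt.fit(short_run.log, "simpleq", cfg)
        assert a.params == b.params
        assert a.loglik == b.loglik and a.aic == b.aic

    def test_aic_identity_holds_exactly(self, short_run):
        fr = pt.fit(short_run.log, "simpleq", pt.FitConfig(n_starts=3, seed=1))
        assert fr.aic == -2.0 * fr.loglik + 2.0 * fr.n_free_params

    def test_best_start_is_reported(self, short_run):
        fr = pt.fit(short_run.log, "simpleq", pt.FitConfig(n_starts=4, seed=2))
        assert -fr.loglik == pytest.approx(min(fr.diagnostics["start_neglls"]))

    def test_fit_beats_generating_parameters(self, short_run, ref_params):
        """The MLE can only improve on the true generating likelihood."""
        fr = pt.fit(short_run.log, "perseverance", pt.FitConfig(n_starts=5, seed=3))
        ll_true = pt.replay_loglik(short_run.log, ref_params, "perseverance").loglik
        assert fr.loglik >= ll_true - 1e-6

    def test_degenerate_single_action_log_warns(self):
        log = _log_from_labels(["ILP"] * 40)
        with pytest.warns(UserWarning, match="degenerate"):
            pt.fit(log, "simpleq", pt.FitConfig(n_starts=2, seed=0))


class TestCompareModels:
    def test_duplicate_kinds_give_identical_rows(self, short_run):
        cmp = pt.compare_models(short_run.log, ["simpleq", "simpleq"],
                                pt.FitConfig(n_starts=3, seed=4))
        t = cmp.table
        assert t.loc[0, "aic"] == t.loc[1, "aic"]
        assert t.loc[0, "winner"] and not t.loc[1, "winner"]  # canonical-order tie-break

    def test_winner_has_zero_delta_aic(self, short_run):
        cmp = pt.compare_models(short_run.log, ["simpleq", "nolearn"],
                                pt.FitConfig(n_starts=3, seed=4))
        winner_row = cmp.table[cmp.table["winner"]].iloc[0]
        assert winner_row["delta_aic"] == 0.0

    def test_needs_two_kinds(self, short_run):
        with pytest.raises(ValueError):
            pt.compare_models(short_run.log, ["simpleq"])
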