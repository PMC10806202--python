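"""Unit and property tests for the model family's policy and update rules."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import prtrace as pt
from prtrace.models import ParameterError, effective_alpha


def _pers(**kw):
    base = dict(alpha=0.1, beta=2.0, q0=(0.0, 0.0, 0.0), tau=0.5, phi=(1.0, -2.0, 0.5))
    base.update(kw)
    return pt.ParamSet(**base)


class TestInitState:
    def test_q_starts_at_q0_and_traces_at_zero(self):
        params = _pers(q0=(0.82, 0.73, 0.23))
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        assert np.allclose(state.q, [0.82, 0.73, 0.23])
        assert np.all(state.c == 0.0)
        assert state.step_index == 0

    def test_zero_q0(self):
        state = pt.init_state(_pers(), pt.ModelKind.PERSEVERANCE)
        assert np.all(state.q == 0.0) and state.c.sum() == 0.0

    @pytest.mark.parametrize("bad_q", [1.5, -1.2, float("nan")])
    def test_q0_outside_unit_box_rejected(self, bad_q):
        with pytest.raises(ParameterError, match="q0"):
            pt.init_state(_pers(q0=(bad_q, 0.0, 0.0)), pt.ModelKind.PERSEVERANCE)

    def test_missing_field_for_kind_rejected(self):
        with pytest.raises(ParameterError, match="tau"):
            pt.init_state(pt.ParamSet(alpha=0.1, beta=1.0), pt.ModelKind.PERSEVERANCE)


class TestActionProbabilities:
    def test_equal_values_give_uniform(self):
        state = pt.init_state(_pers(q0=(0.4, 0.4, 0.4)), pt.ModelKind.PERSEVERANCE)
        p = pt.action_probabilities(state, _pers(q0=(0.4, 0.4, 0.4)), pt.ModelKind.PERSEVERANCE)
        assert np.allclose(p, 1 / 3, atol=1e-15)

    def test_zero_beta_gives_uniform(self):
        params = pt.ParamSet(alpha=0.1, beta=0.0, q0=(0.9, -0.5, 0.1))
        state = pt.init_state(params, pt.ModelKind.SIMPLEQ)
        p = pt.action_probabilities(state, params, pt.ModelKind.SIMPLEQ)
        assert np.allclose(p, 1 / 3, atol=1e-15)

    def test_sharp_softmax_hand_computed(self):
        # direct evaluation of exp(beta*q)/sum at the fitted-regime values
        beta, q = 14.8, np.array([0.82, 0.73, 0.23])
        expected = np.exp(beta * q) / np.exp(beta * q).sum()
        params = pt.ParamSet(alpha=0.1, beta=beta, q0=tuple(q))
        state = pt.init_state(params, pt.ModelKind.SIMPLEQ)
        p = pt.action_probabilities(state, params, pt.ModelKind.SIMPLEQ)
        assert np.allclose(p, expected, atol=1e-12)
        assert p.argmax() == pt.Action.ALP

    def test_nonfinite_logits_identified(self):
        params = _pers()
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        state.q[0] = np.inf
        with pytest.raises(ParameterError, match="beta"):
            pt.action_probabilities(state, params, pt.ModelKind.PERSEVERANCE)

    @given(
        q=st.lists(st.floats(-1, 1), min_size=3, max_size=3),
        c=st.lists(st.floats(0, 1), min_size=3, max_size=3),
        beta=st.floats(0, 50),
    )
    def test_normalization_and_positivity(self, q, c, beta):
        params = _pers(beta=beta)
        state = pt.AgentState(np.array(q), np.array(c))
        p = pt.action_probabilities(state, params, pt.ModelKind.PERSEVERANCE)
        assert abs(p.sum() - 1.0) < 1e-12
        assert np.all(p > 0)

    @given(shift=st.floats(-30, 30), beta=st.floats(0, 20))
    def test_shift_invariance_of_logits(self, shift, beta):
        # adding a constant to every logit must not change the policy;
        # realized here by shifting all three q0 equally (logits = beta*q)
        q = np.array([0.3, -0.2, 0.6])
        pa = pt.ParamSet(alpha=0.1, beta=beta, q0=tuple(q))
        sa = pt.init_state(pa, pt.ModelKind.SIMPLEQ)
        sb = pt.AgentState(q + (shift / max(beta, 1e-9) if beta else 0.0), np.zeros(3))
        p1 = pt.action_probabilities(sa, pa, pt.ModelKind.SIMPLEQ)
        p2 = pt.action_probabilities(sb, pa, pt.ModelKind.SIMPLEQ)
        assert np.allclose(p1, p2, atol=1e-9)


class TestUpdate:
    def test_one_step_value_arithmetic(self):
        params = pt.ParamSet(alpha=0.1, beta=1.0, q0=(0.0, 0.5, 0.0))
        state = pt.init_state(params, pt.ModelKind.SIMPLEQ)
        new, rpe = pt.update(state, pt.Action.MNP, pt.Outcome(1), params, pt.ModelKind.SIMPLEQ)
        assert rpe == pytest.approx(0.5)
        assert new.q[pt.Action.MNP] == pytest.approx(0.55)
        assert new.q[pt.Action.ALP] == 0.0 and new.q[pt.Action.ILP] == 0.0
        assert new.step_index == 1

    def test_trace_jump_on_first_choice(self):
        params = _pers(tau=0.69)
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        new, _ = pt.update(state, pt.Action.ALP, pt.Outcome(0), params, pt.ModelKind.PERSEVERANCE)
        assert np.allclose(new.c, [0.69, 0.0, 0.0])

    def test_unchosen_trace_decays_geometrically(self):
        params = _pers(tau=0.5)
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        state.c = np.array([0.0, 0.5, 0.0])
        new, _ = pt.update(state, pt.Action.ALP, pt.Outcome(0), params, pt.ModelKind.PERSEVERANCE)
        assert new.c[pt.Action.MNP] == pytest.approx(0.25)

    def test_repeated_choice_drives_trace_to_one(self):
        params = _pers(tau=0.3)
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        prev = 0.0
        for _ in range(60):
            state, _ = pt.update(state, pt.Action.ALP, pt.Outcome(0), params,
                                 pt.ModelKind.PERSEVERANCE)
            assert state.c[0] > prev
            prev = state.c[0]
        assert prev == pytest.approx(1.0, abs=1e-6)

    def test_nolearn_freezes_values_but_traces_move(self):
        params = pt.ParamSet(beta=1.0, q0=(0.5, 0.5, 0.5), tau=0.4, phi=(0.0, 0.0, 0.0))
        state = pt.init_state(params, pt.ModelKind.NOLEARN)
        new, rpe = pt.update(state, pt.Action.MNP, pt.Outcome(1), params, pt.ModelKind.NOLEARN)
        assert np.allclose(new.q, state.q)
        assert rpe == pytest.approx(0.5)
        assert new.c[pt.Action.MNP] == pytest.approx(0.4)

    @pytest.mark.parametrize(
        "q_chosen,r,expected_sign", [(0.3, 1, 1), (0.3, 0, -1), (-0.2, 0, 1), (1.0, 1, 0)]
    )
    def test_rpe_sign_matches_value_gap(self, q_chosen, r, expected_sign):
        params = pt.ParamSet(alpha=0.1, beta=1.0, q0=(q_chosen, 0.0, 0.0))
        state = pt.init_state(params, pt.ModelKind.SIMPLEQ)
        _, rpe = pt.update(state, pt.Action.ALP, pt.Outcome(r), params, pt.ModelKind.SIMPLEQ)
        assert np.sign(rpe) == expected_sign

    def test_asymmetry_tie_break_uses_positive_rate(self):
        params = pt.ParamSet(alpha_pos=0.4, alpha_neg=0.1, beta=1.0, q0=(0.0, 0.0, 0.0))
        assert effective_alpha(params, pt.ModelKind.ASYMMETRY, 0.0) == 0.4

    @given(
        tau=st.floats(0, 1),
        choices=st.lists(st.integers(0, 2), min_size=1, max_size=80),
    )
    def test_traces_stay_in_unit_interval(self, tau, choices):
        params = _pers(tau=tau)
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        for ch in choices:
            state, _ = pt.update(state, pt.Action(ch), pt.Outcome(0), params,
                                 pt.ModelKind.PERSEVERANCE)
            assert np.all(state.c >= 0.0) and np.all(state.c <= 1.0)

    def test_negative_tau_smoke(self):
        # permitted by the parameter bounds; same formula, no range guarantee
        params = _pers(tau=-0.5)
        state = pt.init_state(params, pt.ModelKind.PERSEVERANCE)
        state, _ = pt.update(state, pt.Action.ALP, pt.Outcome(0), params,
                             pt.ModelKind.PERSEVERANCE)
        assert state.c[0] == pytest.approx(-0.5)


class TestNesting:
    """The four variants are nested; matched parameters must give identical
    policies at every step of any event sequence."""

    @pytest.mark.parametrize(
        "kind_a,params_a,kind_b,params_b",
        [
            (  # perseverance with phi=0 collapses to simpleq
                pt.ModelKind.PERSEVERANCE,
                pt.ParamSet(alpha=0.2, beta=3.0, q0=(0.5, -0.1, 0.2), tau=0.6, phi=(0, 0, 0)),
                pt.ModelKind.SIMPLEQ,
                pt.ParamSet(alpha=0.2, beta=3.0, q0=(0.5, -0.1, 0.2)),
            ),
            (  # asymmetry with equal rates collapses to simpleq
                pt.ModelKind.ASYMMETRY,
                pt.ParamSet(alpha_pos=0.2, alpha_neg=0.2, beta=3.0, q0=(0.5, -0.1, 0.2)),
                pt.ModelKind.SIMPLEQ,
                pt.ParamSet(alpha=0.2, beta=3.0, q0=(0.5, -0.1, 0.2)),
            ),
            (  # perseverance with alpha=0 collapses to nolearn
                pt.ModelKind.PERSEVERANCE,
                pt.ParamSet(alpha=0.0, beta=3.0, q0=(0.5, -0.1, 0.2), tau=0.6, phi=(1, -2, 0.5)),
                pt.ModelKind.NOLEARN,
                pt.ParamSet(beta=3.0, q0=(0.5, -0.1, 0.2), tau=0.6, phi=(1, -2, 0.5)),
            ),
        ],
    )
    def test_matched_models_agree_stepwise(self, kind_a, params_a, kind_b, params_b):
        rng = np.random.default_rng(5)
        sa = pt.init_state(params_a, kind_a)
        sb = pt.init_state(params_b, kind_b)
        for _ in range(120):
            pa = pt.action_probabilities(sa, params_a, kind_a)
            pb = pt.action_probabilities(sb, params_b, kind_b)
            assert np.allclose(pa, pb, atol=1e-14)
            ch = pt.Action(rng.integers(0, 3))
            r = pt.Outcome(int(rng.random() < 0.1))
            sa, _ = pt.update(sa, ch, r, params_a, kind_a)
            sb, _ = pt.update(sb, ch, r, params_b, kind_b)


class TestSerialization:
    @pytest.mark.parametrize(
        "kind,params",
        [
            (pt.ModelKind.SIMPLEQ, pt.ParamSet(alpha=0.05, beta=12.0, q0=(0.7, 0.5, 0.2))),
            (pt.ModelKind.PERSEVERANCE,
             pt.ParamSet(alpha=6.8e-4, beta=14.8, q0=(0.82, 0.73, 0.23), tau=0.69,
                         phi=(-0.1, -16.6, 3.0))),
        ],
    )
    def test_flat_json_round_trip(self, kind, params):
        back = pt.ParamSet.from_json(params.to_json())
        assert back == params

    def test_absent_keys_mean_not_applicable(self):
        d = pt.ParamSet(alpha=0.1, beta=2.0, q0=(0, 0, 0)).to_dict()
        assert "tau" not in d and "phi_ALP" not in d

    def test_outcome_must_be_binary(self):
        with pytest.raises(ValueError):
            pt.Outcome(2)
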