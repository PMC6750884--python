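import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import twostage as ts
from twostage import _kernel
from twostage.agents import (
    SEQUENCES,
    AgentState,
    ImpossibleObservation,
    ModelSpec,
    Responsibilities,
    SpecError,
    resolve_params,
)
from twostage.task import TaskConfig, Trial

from .conftest import random_params
from .oracles import enum_trial_prob


def make_trial(a1="L", s2="S2", a2="R", outcome=1, transition="common"):
    return Trial("s", 0, "probe", 0, a1, s2, a2, outcome, transition)


class TestModelSpec:
    def test_option_sets_per_family(self):
        assert ModelSpec("FLAT").option_set() == ("L", "R")
        assert ModelSpec("MB").option_set() == ("L", "R")
        assert ModelSpec("H").option_set() == ("L->R", "R->L")
        assert ModelSpec("H-MB").option_set() == ("L", "R", "L->R", "R->L")

    def test_inapplicable_toggles_rejected(self):
        with pytest.raises(SpecError):
            ModelSpec("MB", interruption=True)
        with pytest.raises(SpecError):
            ModelSpec("FLAT", disc_bias=True)
        with pytest.raises(SpecError):
            ModelSpec("MB", eligibility=True)
        with pytest.raises(SpecError):
            ModelSpec("H", learn_transitions=True)

    def test_pure_sequence_family_needs_escape_hatch(self):
        with pytest.raises(SpecError):
            ModelSpec("H", interruption=False)
        # a positive fixed interruption probability or a lapse floor is enough
        ModelSpec("H", interruption=False, fixed={"p_int": 0.1})
        ModelSpec("H", interruption=False, lapse=True)

    def test_fixed_values_removed_from_free_set(self):
        spec = ModelSpec("MB", fixed={"beta2": 3.0})
        assert "beta2" not in spec.free_params()
        assert spec.df == 3

    def test_shared_alpha_fills_all_rates(self):
        p = resolve_params(ModelSpec("H-MB"), dict(
            alpha=0.3, beta1=1.0, beta2=1.0, p_int=0.1, b_disc=0.0))
        assert p.alpha1 == p.alpha2 == p.alpha_seq == 0.3

    def test_separate_alphas_expand_free_set(self):
        spec = ModelSpec("H-MB-MF", separate_alphas=True)
        free = spec.free_params()
        assert {"alpha1", "alpha2", "alpha_seq"} <= set(free)
        assert "alpha" not in free


class TestStage1Values:
    def test_mb_planning_with_deterministic_transition(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1, b_disc=0))
        state = AgentState.init(spec, params)
        state.T[0] = (0.0, 1.0)      # L surely reaches S2
        state.Q2[1] = (0.2, 0.6)     # S2 values; max picks 0.6
        vals = ts.stage1_values(spec, params, state)
        assert vals["L"] == pytest.approx(0.6)

    def test_hybrid_is_convex_combination(self):
        spec = ModelSpec("MB-MF")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1, w=0.5, b_disc=0))
        state = AgentState.init(spec, params)
        state.T[0] = (0.0, 1.0)
        state.Q2[1] = (0.2, 0.6)
        state.Q1mf[0] = 0.2
        vals = ts.stage1_values(spec, params, state)
        assert vals["L"] == pytest.approx(0.5 * 0.6 + 0.5 * 0.2)

    def test_tied_stage2_values_average(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1, b_disc=0))
        state = AgentState.init(spec, params)
        state.T[0] = (0.0, 1.0)
        state.Q2[1] = (0.4, 0.4)
        assert ts.stage1_values(spec, params, state)["L"] == pytest.approx(0.4)

    def test_h_mb_exposes_four_options(self):
        spec = ModelSpec("H-MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1,
                                           p_int=0.1, b_disc=0))
        vals = ts.stage1_values(spec, params, AgentState.init(spec, params))
        assert set(vals) == {"L", "R", "L->R", "R->L"}


class TestPolicies:
    def test_equal_values_give_uniform_policy(self):
        spec = ModelSpec("H-MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=3.0, beta2=1,
                                           p_int=0.1, b_disc=0))
        pol = ts.stage1_policy(spec, params, AgentState.init(spec, params))
        assert all(p == pytest.approx(0.25) for p in pol.values())

    def test_zero_temperature_gives_uniform_policy(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=0.0, beta2=1, b_disc=0))
        state = AgentState.init(spec, params)
        state.Q2[1] = (0.0, 1.0)
        pol = ts.stage1_policy(spec, params, state)
        assert pol["L"] == pytest.approx(0.5)

    def test_softmax_matches_hand_evaluated_logistic(self):
        # two options with values 0.6 and 0.2 at inverse temperature 2:
        # P(first) = 1 / (1 + exp(-2 * 0.4)) ~= 0.690
        spec = ModelSpec("MF")
        params = resolve_params(spec, dict(alpha=0.5, beta1=2.0, beta2=1, b_disc=0))
        state = AgentState.init(spec, params)
        state.Q1mf[:] = (0.6, 0.2)
        pol = ts.stage1_policy(spec, params, state)
        assert pol["L"] == pytest.approx(1 / (1 + math.exp(-0.8)), abs=1e-6)

    def test_stage2_hand_evaluated_logistic(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=2.0, b_disc=0))
        state = AgentState.init(spec, params)
        state.Q2[1] = (0.2, 0.6)  # S2: Q(L)=0.2, Q(R)=0.6
        pol = ts.stage2_policy("S2", spec, params, state)
        assert pol["R"] == pytest.approx(1 / (1 + math.exp(-0.8)), abs=1e-6)

    def test_large_disc_bias_dominates(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1, b_disc=50.0))
        state = AgentState.init(spec, params)
        assert ts.stage2_policy("S2", spec, params, state)["R"] > 0.999
        assert ts.stage2_policy("S1", spec, params, state)["L"] > 0.999

    def test_equal_values_no_bias_is_even(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=3, b_disc=0))
        pol = ts.stage2_policy("S1", spec, params, AgentState.init(spec, params))
        assert pol["L"] == pytest.approx(0.5)

    @pytest.mark.parametrize("family", ts.FAMILIES)
    def test_policies_are_normalised(self, family, rng):
        spec = ModelSpec(family)
        for _ in range(20):
            params = random_params(spec, rng)
            state = AgentState.init(spec, params)
            assert sum(ts.stage1_policy(spec, params, state).values()) == pytest.approx(1.0, abs=1e-12)
            assert sum(ts.stage2_policy("S1", spec, params, state).values()) == pytest.approx(1.0, abs=1e-12)


class TestTrialLoglik:
    def test_no_sequence_family_factorises(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=2, beta2=3, b_disc=1))
        state = AgentState.init(spec, params)
        trial = make_trial()
        ll, resp = ts.trial_loglik(trial, spec, params, state)
        p1 = ts.stage1_policy(spec, params, state)["L"]
        p2 = ts.stage2_policy("S2", spec, params, state)["R"]
        assert ll == pytest.approx(math.log(p1) + math.log(p2))
        assert resp.p_sequence == 0.0

    def test_pure_sequences_incomplete_observation_is_impossible(self):
        spec = ModelSpec("H", interruption=False, fixed={"p_int": 0.0, "eps": 0.0})
        params = resolve_params(spec, dict(alpha=0.5, beta1=2, beta2=3, b_disc=0))
        state = AgentState.init(spec, params)
        # a1=L starts L->R, so a2 must be R; observing L is impossible
        trial = make_trial(a1="L", s2="S2", a2="L", outcome=0)
        with pytest.raises(ImpossibleObservation):
            ts.trial_loglik(trial, spec, params, state)

    def test_aborted_trial_must_be_excluded_by_caller(self):
        spec = ModelSpec("MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=2, beta2=3, b_disc=1))
        trial = Trial("s", 0, "probe", 0, "L", "S2", None, 0, "common", aborted=True)
        with pytest.raises(ValueError):
            ts.trial_loglik(trial, spec, params, AgentState.init(spec, params))

    @pytest.mark.parametrize("family", ts.FAMILIES)
    def test_matches_brute_force_enumeration(self, family, rng):
        """The marginal over latent modes equals exhaustive enumeration."""
        spec = ModelSpec(family)
        for _ in range(100):
            params = random_params(spec, rng)
            state = AgentState.init(spec, params)
            state.Q2[:] = rng.uniform(0, 1, (2, 2))
            state.Q1mf[:] = rng.uniform(0, 1, 2)
            state.Qseq[:] = rng.uniform(0, 1, 2)
            state.Qflat[:] = rng.uniform(0, 1, 2)
            trial = make_trial(
                a1="LR"[rng.integers(2)],
                s2=("S1", "S2")[rng.integers(2)],
                a2="LR"[rng.integers(2)],
                outcome=int(rng.integers(2)),
            )
            ll, _ = ts.trial_loglik(trial, spec, params, state)
            assert math.exp(ll) == pytest.approx(
                enum_trial_prob(trial, spec, params, state), abs=1e-10
            )

    def test_responsibilities_form_a_posterior(self, rng):
        spec = ModelSpec("H-MB")
        for _ in range(50):
            params = random_params(spec, rng)
            state = AgentState.init(spec, params)
            state.Qseq[:] = rng.uniform(0, 1, 2)
            trial = make_trial(a2="LR"[rng.integers(2)])
            _, resp = ts.trial_loglik(trial, spec, params, state)
            assert 0.0 <= resp.p_completed <= resp.p_sequence <= 1.0
            assert resp.p_stage2_choice == pytest.approx(1.0 - resp.p_completed)


class TestUpdate:
    def _mb_setup(self):
        spec = ModelSpec("MB", learn_transitions=True)
        params = resolve_params(
            spec, dict(alpha=1.0, beta1=1, beta2=1, b_disc=0, alpha_T=0.5)
        )
        return spec, params, AgentState.init(spec, params)

    def test_full_learning_rate_jumps_to_reward(self):
        spec, params, state = self._mb_setup()
        new = ts.update(state, make_trial(outcome=1), Responsibilities(0, 0), spec, params)
        assert new.Q2[1, 1] == 1.0

    def test_zero_learning_rates_leave_state_unchanged(self):
        spec = ModelSpec("H-MB-MF", learn_transitions=True)
        params = resolve_params(spec, dict(
            alpha=0.0, alpha_T=0.0, beta1=1, beta2=1, w=0.5, p_int=0.1, b_disc=0))
        state = AgentState.init(spec, params)
        new = ts.update(state, make_trial(), Responsibilities(1.0, 1.0), spec, params)
        for field in ("Q2", "Q1mf", "T", "Qseq", "Qflat"):
            assert np.array_equal(getattr(new, field), getattr(state, field))

    def test_sequence_update_weighted_by_responsibility(self):
        spec = ModelSpec("H-MB")
        params = resolve_params(spec, dict(alpha=0.5, beta1=1, beta2=1,
                                           p_int=0.1, b_disc=0))
        state = AgentState.init(spec, params)
        trial = make_trial(outcome=1)
        full = ts.update(state, trial, Responsibilities(1.0, 1.0), spec, params)
        none = ts.update(state, trial, Responsibilities(0.0, 0.0), spec, params)
        expected = state.Qseq[0] + 0.5 * (1 - state.Qseq[0])
        assert full.Qseq[0] == pytest.approx(expected)
        assert none.Qseq[0] == state.Qseq[0]

    def test_transition_rows_stay_normalised(self):
        spec, params, state = self._mb_setup()
        new = ts.update(state, make_trial(), Responsibilities(0, 0), spec, params)
        assert new.T.sum(axis=1) == pytest.approx(np.ones(2))
        assert new.T[0, 1] > state.T[0, 1]

    def test_flat_reinforces_proximal_action_only(self):
        spec = ModelSpec("FLAT")
        params = resolve_params(spec, dict(alpha1=0.5, beta1=1))
        state = AgentState.init(spec, params)
        trial = make_trial(a1="L", a2="R", outcome=1)
        new = ts.update(state, trial, Responsibilities(0, 0), spec, params)
        assert new.Qflat[1] > state.Qflat[1]   # rewarded proximal press goes up
        assert new.Qflat[0] < state.Qflat[0]   # distal press extinguishes

    @pytest.mark.parametrize("family", ts.FAMILIES)
    def test_values_stay_in_unit_interval(self, family, rng):
        """With binary rewards and rates in [0,1], all values remain in [0,1]."""
        spec = ModelSpec(family)
        params = random_params(spec, rng)
        state = AgentState.init(spec, params)
        for _ in range(200):
            trial = make_trial(
                a1="LR"[rng.integers(2)], s2=("S1", "S2")[rng.integers(2)],
                a2="LR"[rng.integers(2)], outcome=int(rng.integers(2)),
            )
            try:
                _, resp = ts.trial_loglik(trial, spec, params, state)
            except ImpossibleObservation:
                continue
            state = ts.update(state, trial, resp, spec, params)
            for arr in (state.Q2, state.Q1mf, state.Qseq, state.Qflat, state.T):
                assert np.all(arr >= 0.0) and np.all(arr <= 1.0)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(
    family=st.sampled_from(ts.FAMILIES),
    seed=st.integers(0, 2**20),
    n=st.integers(1, 12),
)
def test_kernel_matches_python_reference(family, seed, n):
    """The compiled session likelihood equals the step-by-step reference."""
    rng = np.random.default_rng(seed)
    spec = ModelSpec(family)
    params = random_params(spec, rng)
    cfg = TaskConfig(p_common=0.8, phase="probe", max_outcomes=n, max_trials=n)
    sess = ts.run_session(ts.SimAgent(spec, params), cfg, rng)
    if not sess.trials:
        return
    state = AgentState.init(spec, params)
    nll_py = 0.0
    for t in sess.trials:
        ll, resp = ts.trial_loglik(t, spec, params, state)
        nll_py -= ll
        state = ts.update(state, t, resp, spec, params)
    arrs = _kernel.session_arrays(sess.to_dataframe())
    assert _kernel.dataset_nll(spec, params, [arrs]) == pytest.approx(nll_py, abs=1e-10)


class TestSimulatedSignatures:
    def test_flat_agent_repeats_previously_rewarded_proximal_action(self):
        """The mechanism behind the negative early-training stay effect."""
        rng = np.random.default_rng(4)
        spec = ModelSpec("FLAT")
        params = resolve_params(spec, dict(alpha1=0.5, beta1=4.0))
        agent = ts.SimAgent(spec, params)
        cfg = TaskConfig(max_outcomes=10**9, max_trials=2000)
        sess = ts.run_session(agent, cfg, rng)
        repeats = total = 0
        for prev, cur in zip(sess.trials, sess.trials[1:]):
            if prev.outcome == 1:
                total += 1
                repeats += cur.a1 == prev.a2
        assert total > 50
        assert repeats / total > 0.5

    def test_uninterrupted_sequences_complete_even_after_rare_transitions(self):
        rng = np.random.default_rng(5)
        spec = ModelSpec("H-MB", interruption=False, fixed={"p_int": 0.0, "eps": 1e-3},
                         lapse=True)
        params = resolve_params(spec, dict(alpha=0.5, beta1=3, beta2=3, b_disc=1))
        agent = ts.SimAgent(spec, params)
        agent.begin_session(TaskConfig(p_common=0.5, phase="probe"))
        cfg = TaskConfig(p_common=0.5, phase="probe")
        checked = 0
        for _ in range(400):
            a1 = agent.act_stage1(rng)
            s2, label = ts.transition(a1, cfg, rng)
            a2 = agent.act_stage2(s2, rng)
            if agent._mode in SEQUENCES and label == "rare":
                assert a2 == agent._mode.split("->")[1]
                checked += 1
            r = ts.outcome(s2, a2, "S2")
            agent.learn(Trial("s", 0, "probe", 0, a1, s2, a2, r, label))
        assert checked > 20
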