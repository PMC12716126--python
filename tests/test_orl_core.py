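import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from orligt import (
    ORLParams,
    SubjectTrials,
    choice_probs,
    deck_values,
    init_state,
    make_classic_schedule,
    pointwise_loglik_matrix,
    sequence_loglik,
    simulate_agent,
    trial_loglik,
    update_state,
)
from orligt.orl_core import InvalidOutcomeError, _pointwise_numpy

from conftest import naive_orl_loglik

LN4 = np.log(4.0)


def _params(**kw):
    base = dict(a_rew=0.3, a_pun=0.1, k_prime=0.5, beta_f=1.0, beta_p=0.5)
    base.update(kw)
    return ORLParams(**base)


class TestParamsAndState:
    def test_param_bounds_enforced(self):
        with pytest.raises(ValueError):
            ORLParams(a_rew=1.2, a_pun=0.1, k_prime=0.5, beta_f=0, beta_p=0)
        with pytest.raises(ValueError):
            ORLParams(a_rew=0.2, a_pun=0.1, k_prime=-0.1, beta_f=0, beta_p=0)

    def test_memory_decay_derivation(self):
        assert _params(k_prime=0.0).k == 0.0
        assert _params(k_prime=1.0).k == pytest.approx(2.0)

    def test_init_state_is_all_zero_and_symmetric(self):
        state = init_state()
        assert np.all(state.ev == 0) and np.all(state.ef == 0) and np.all(state.ps == 0)
        v = deck_values(state, _params())
        assert np.all(v == v[0])
        assert np.allclose(choice_probs(v), 0.25)


class TestUpdateState:
    def test_single_step_arithmetic(self):
        # one positive unit outcome on deck 1 with A_rew=.5, A_pun=.3, K'=1
        params = _params(a_rew=0.5, a_pun=0.3, k_prime=1.0)
        state = update_state(init_state(), 1, 1.0, params)
        assert np.allclose(state.ev, [0.5, 0, 0, 0])
        assert np.allclose(state.ef, [0.5, -0.1, -0.1, -0.1])
        assert np.allclose(state.ps, [1 / 3, 0, 0, 0])

    def test_zero_outcome_takes_reward_branch(self):
        params = _params(a_rew=0.4)
        start = update_state(init_state(), 2, 1.0, params)  # give EF_2 some mass
        ef_before = start.ef[1]
        after = update_state(start, 2, 0.0, params)
        # sgn(0)=0: chosen EF decays toward 0 by (1 - A_rew)
        assert after.ef[1] == pytest.approx(ef_before * (1 - params.a_rew))
        assert after.ev[1] == pytest.approx(start.ev[1] * (1 - params.a_rew))

    def test_no_decay_when_k_prime_zero(self):
        params = _params(k_prime=0.0)
        s1 = update_state(init_state(), 1, 1.0, params)
        s2 = update_state(s1, 2, 1.0, params)
        assert s2.ps[1] == 1.0  # chosen: 1/(1+0)
        assert s2.ps[0] == s1.ps[0]  # unchosen unchanged

    def test_update_is_pure(self):
        state = init_state()
        update_state(state, 1, 1.0, _params())
        assert np.all(state.ev == 0) and np.all(state.ef == 0) and np.all(state.ps == 0)

    def test_only_chosen_ev_changes(self):
        state = update_state(init_state(), 3, -2.0, _params())
        assert state.ev[2] != 0
        assert np.all(state.ev[[0, 1, 3]] == 0)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            update_state(init_state(), 0, 1.0, _params())
        with pytest.raises(InvalidOutcomeError):
            update_state(init_state(), 1, np.nan, _params())

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=30, deadline=None)
    def test_ef_and_ps_stay_bounded(self, seed):
        """From zero init, EF stays in [-1,1] and PS in [0,1] for any params."""
        rng = np.random.default_rng(seed)
        params = ORLParams(
            a_rew=rng.uniform(0, 1), a_pun=rng.uniform(0, 1),
            k_prime=rng.uniform(0, 4), beta_f=rng.normal(0, 3), beta_p=rng.normal(0, 3),
        )
        state = init_state()
        for _ in range(50):
            choice = int(rng.integers(1, 5))
            x = float(rng.normal(0, 5))
            state = update_state(state, choice, x, params)
            assert np.all(state.ef >= -1 - 1e-12) and np.all(state.ef <= 1 + 1e-12)
            assert np.all(state.ps >= 0) and np.all(state.ps <= 1 + 1e-12)

    def test_reward_rate_monotonically_scales_ev_step(self):
        # larger A_rew => strictly larger one-step EV increment after a gain
        increments = [
            update_state(init_state(), 1, 0.8, _params(a_rew=a)).ev[0]
            for a in (0.1, 0.3, 0.7, 0.95)
        ]
        assert np.all(np.diff(increments) > 0)


class TestChoiceRule:
    def test_deck_values_linear_combination(self):
        state = init_state()
        state = update_state(state, 1, 1.0, _params(a_rew=0.2, a_pun=0.5, k_prime=0.0))
        v = deck_values(state, _params(beta_f=2.0, beta_p=-1.0))
        # EV=(0.2,..), EF=(0.2*1,..)*2, PS=(1,..)*-1 on the chosen deck
        assert v[0] == pytest.approx(0.2 + 2 * 0.2 - 1.0)

    def test_softmax_closed_form(self):
        p = choice_probs(np.array([np.log(2), 0, 0, 0]))
        assert np.allclose(p, [0.4, 0.2, 0.2, 0.2])

    def test_softmax_shift_invariance_and_normalization(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            v = rng.normal(0, 10, 4)
            p = choice_probs(v)
            assert abs(p.sum() - 1.0) < 1e-12
            assert np.allclose(p, choice_probs(v + 123.4), atol=1e-12)

    def test_softmax_stable_for_large_values(self):
        p = choice_probs(np.array([1e4, 0.0, 0.0, 0.0]))
        assert np.isfinite(p).all() and p[0] == pytest.approx(1.0)

    def test_softmax_rejects_non_finite(self):
        with pytest.raises(ValueError):
            choice_probs(np.array([np.inf, 0, 0, 0]))

    def test_trial_loglik_uniform_at_init(self):
        for c in range(1, 5):
            assert trial_loglik(init_state(), c, _params()) == pytest.approx(-LN4)

    def test_trial_loglik_exponentiates_to_softmax(self):
        state = update_state(init_state(), 1, 1.0, _params())
        params = _params()
        p = choice_probs(deck_values(state, params))
        for c in range(1, 5):
            assert np.exp(trial_loglik(state, c, params)) == pytest.approx(p[c - 1], abs=1e-12)


class TestSequenceLoglik:
    def test_null_parameters_give_pure_chance(self):
        rng = np.random.default_rng(1)
        trials = SubjectTrials(
            "s", rng.integers(1, 5, 100), rng.uniform(10, 100, 100), np.zeros(100)
        )
        null = ORLParams(0.0, 0.0, 0.0, 0.0, 0.0)
        total, pointwise = sequence_loglik(trials, null)
        assert total == pytest.approx(-100 * LN4)
        assert np.allclose(pointwise, -LN4)

    def test_first_trial_is_always_uniform(self):
        trials = SubjectTrials("s", [3], [50.0], [0.0])
        total, _ = sequence_loglik(trials, _params())
        assert total == pytest.approx(-LN4)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            sequence_loglik(SubjectTrials("s", [], [], []), _params())

    def test_matches_naive_oracle_on_fixed_sequence(self):
        rng = np.random.default_rng(3)
        choices = rng.integers(1, 5, 20)
        gains = rng.choice([50.0, 100.0], 20)
        losses = rng.choice([0.0, 0.0, 250.0, 1250.0], 20)
        params = _params(a_rew=0.4, a_pun=0.1, k_prime=0.5, beta_f=1.0, beta_p=0.5)
        _, pointwise = sequence_loglik(SubjectTrials("s", choices, gains, losses), params)
        expected = naive_orl_loglik(choices, gains, losses, 0.4, 0.1, 0.5, 1.0, 0.5)
        assert np.allclose(pointwise, expected, atol=1e-10)


class TestVectorizedLikelihood:
    def test_matrix_agrees_with_scalar_path(self, classic_schedule, random_params):
        rng = np.random.default_rng(5)
        subset = random_params[:20]
        trials = [
            simulate_agent(ORLParams(**p), classic_schedule, 50, seed=i)
            for i, p in enumerate(subset)
        ]
        choices = np.array([t.choices for t in trials])
        nets = np.array([t.net for t in trials])
        arr = np.array([[p[k] for k in ("a_rew", "a_pun", "k_prime", "beta_f", "beta_p")] for p in subset])
        M = pointwise_loglik_matrix(choices, nets, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3], arr[:, 4])
        for i, (t, p) in enumerate(zip(trials, subset)):
            _, pw = sequence_loglik(t, ORLParams(**p))
            assert np.allclose(M[i], pw, atol=1e-10)

    def test_numba_kernel_matches_numpy_fallback(self, classic_schedule):
        rng = np.random.default_rng(6)
        trials = [simulate_agent(_params(), classic_schedule, 40, seed=i) for i in range(5)]
        choices = np.array([t.choices for t in trials])
        nets = np.array([t.net for t in trials])
        args = (choices, nets, np.full(5, 0.3), np.full(5, 0.1), np.full(5, 0.5),
                np.full(5, 1.0), np.full(5, 0.5))
        assert np.allclose(pointwise_loglik_matrix(*args), _pointwise_numpy(*args), atol=1e-12)


class TestSimulateAgent:
    def test_null_agent_chooses_uniformly(self, classic_schedule):
        null = ORLParams(0.0, 0.0, 0.0, 0.0, 0.0)
        trials = simulate_agent(null, classic_schedule, 10000, seed=0)
        fractions = np.bincount(trials.choices, minlength=5)[1:] / 10000
        se = np.sqrt(0.25 * 0.75 / 10000)
        assert np.all(np.abs(fractions - 0.25) < 3 * se)

    def test_extreme_perseveration_repeats_first_choice(self, classic_schedule):
        sticky = ORLParams(0.0, 0.0, 0.0, 0.0, 50.0)
        trials = simulate_agent(sticky, classic_schedule, 200, seed=1)
        repeats = np.mean(trials.choices[1:] == trials.choices[0])
        assert repeats >= 0.99

    def test_seed_reproducibility(self, classic_schedule):
        a = simulate_agent(_params(), classic_schedule, 100, seed=9)
        b = simulate_agent(_params(), classic_schedule, 100, seed=9)
        assert np.array_equal(a.choices, b.choices)
        assert np.array_equal(a.losses, b.losses)

    def test_outcomes_follow_deck_schedule(self, classic_schedule):
        trials = simulate_agent(_params(), classic_schedule, 100, seed=2)
        # every deck-D draw pays 50; k-th draw from D matches the cycle
        d_losses = trials.losses[trials.choices == 4]
        expected = [0.0] * 9 + [250.0]
        for k, loss in enumerate(d_losses):
            assert loss == expected[k % 10]
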