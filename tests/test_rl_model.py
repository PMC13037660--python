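"""Hybrid two-step model: walk invariants, hand-worked updates, the
likelihood against a brute-force enumeration oracle, and structural
invariances of the choice model."""

import math

import numpy as np
import pytest

from cravemod.errors import ConfigError, DataError
from cravemod.rl import (
    HybridState,
    RLParams,
    TransitionModel,
    gaussian_walk,
    hybrid_update,
    negloglik,
    simulate_agent,
    stage1_probs,
    stage2_probs,
)


class TestGaussianWalk:
    def test_zero_sd_is_constant(self):
        w = gaussian_walk(50, sd=0.0, seed=0)
        assert np.allclose(w, w[0])

    @pytest.mark.parametrize("seed", [0, 1, 2, 99])
    def test_bounds_respected(self, seed):
        w = gaussian_walk(2000, seed=seed)
        assert w.min() >= 0.25 and w.max() <= 0.75

    def test_interior_step_sd_matches_spec(self):
        w = gaussian_walk(100_000, seed=7)
        steps = np.diff(w, axis=0)
        interior = ((w[:-1] > 0.30) & (w[:-1] < 0.70)
                    & (w[1:] > 0.30) & (w[1:] < 0.70))
        assert steps[interior].std() == pytest.approx(0.025, rel=0.05)

    def test_bad_bounds_rejected(self):
        with pytest.raises(ConfigError):
            gaussian_walk(10, bounds=(0.75, 0.25))


class TestHybridUpdate:
    def test_zero_learning_rates_freeze_values(self):
        p = RLParams(alpha1=0.0, alpha2=0.0)
        s = HybridState.initial()
        s2 = hybrid_update(s, (0, 1, 1, 1), p)
        assert np.array_equal(s2.q2, s.q2) and np.array_equal(s2.q1mf, s.q1mf)

    def test_hand_worked_single_trial(self):
        # alpha1 = alpha2 = 0.5, lam = 1, r = 1, all Q start at 0.5:
        # d2 = 0.5 -> Q2 = 0.75; d1 = 0 -> Q1MF += 0.5 * (0 + 0.5) = 0.75
        p = RLParams(alpha1=0.5, alpha2=0.5, lam=1.0)
        s = hybrid_update(HybridState.initial(), (0, 1, 0, 1), p)
        assert s.q2[1, 0] == pytest.approx(0.75)
        assert s.q1mf[0] == pytest.approx(0.75)
        assert s.q2[0, 0] == 0.5 and s.q1mf[1] == 0.5

    def test_w_one_ignores_model_free(self):
        from cravemod.rl import stage1_values

        p = RLParams(w=1.0)
        s = HybridState.initial()
        s.q1mf = np.array([10.0, -10.0])    # extreme MF values
        s.q2 = np.array([[0.6, 0.2], [0.4, 0.3]])
        trans = TransitionModel()
        v = stage1_values(s, p, trans)
        expected = trans.matrix @ s.q2.max(axis=1)
        assert np.allclose(v, expected)

    def test_invalid_trial_rejected(self):
        with pytest.raises(DataError):
            hybrid_update(HybridState.initial(), (2, 0, 0, 1), RLParams())


class TestNegLogLik:
    def test_zero_temperatures_give_uniform_choice(self):
        p = RLParams(beta1=0.0, beta2=0.0, pi=0.0)
        trials = [(0, 1, 0, 1), (1, 0, 1, 0), (0, 0, 0, 1)] * 4
        assert negloglik(p, trials) == pytest.approx(len(trials) * 2 * math.log(2),
                                                     abs=1e-12)

    def test_matches_brute_force_enumeration_on_two_trials(self):
        """Independent oracle: the two-trial likelihood written out by hand,
        with every Q recursion step explicit."""
        p = RLParams(alpha1=0.3, alpha2=0.6, beta1=2.0, beta2=3.0,
                     lam=0.7, w=0.4, pi=0.3)
        trans = TransitionModel()
        m = trans.matrix
        trials = [(0, 1, 1, 1), (1, 0, 0, 0)]

        def softmax_pair(x0, x1, pick):
            z = max(x0, x1)
            den = math.exp(x0 - z) + math.exp(x1 - z)
            return math.exp((x0 if pick == 0 else x1) - z) / den

        q2 = {(0, 0): 0.5, (0, 1): 0.5, (1, 0): 0.5, (1, 1): 0.5}
        q1 = {0: 0.5, 1: 0.5}
        loglik = 0.0
        prev = None
        for (c1, s2, c2, r) in trials:
            best0 = max(q2[(0, 0)], q2[(0, 1)])
            best1 = max(q2[(1, 0)], q2[(1, 1)])
            qmb = {a: m[a, 0] * best0 + m[a, 1] * best1 for a in (0, 1)}
            qnet = {a: p.w * qmb[a] + (1 - p.w) * q1[a] for a in (0, 1)}
            l0 = p.beta1 * qnet[0] + (p.pi if prev == 0 else 0.0)
            l1 = p.beta1 * qnet[1] + (p.pi if prev == 1 else 0.0)
            loglik += math.log(softmax_pair(l0, l1, c1))
            loglik += math.log(
                softmax_pair(p.beta2 * q2[(s2, 0)], p.beta2 * q2[(s2, 1)], c2)
            )
            d2 = r - q2[(s2, c2)]
            d1 = q2[(s2, c2)] - q1[c1]
            q2[(s2, c2)] += p.alpha2 * d2
            q1[c1] += p.alpha1 * (d1 + p.lam * d2)
            prev = c1
        assert negloglik(p, trials, trans) == pytest.approx(-loglik, abs=1e-10)

    def test_softmax_shift_invariance(self):
        p = RLParams(beta1=3.0, beta2=2.0, pi=0.4)
        s = HybridState.initial()
        s.q2 = np.array([[0.6, 0.2], [0.4, 0.3]])
        s.q1mf = np.array([0.7, 0.1])
        s.prev_c1 = 1
        shifted = HybridState(s.q2 + 5.0, s.q1mf + 5.0, s.prev_c1)
        trans = TransitionModel()
        assert np.allclose(stage1_probs(s, p, trans), stage1_probs(shifted, p, trans))
        assert np.allclose(stage2_probs(s, p, 1), stage2_probs(shifted, p, 1))

    def test_choice_probabilities_sum_to_one(self, rng):
        for _ in range(20):
            p = RLParams(
                alpha1=rng.uniform(0, 1), alpha2=rng.uniform(0, 1),
                beta1=rng.uniform(0, 20), beta2=rng.uniform(0, 20),
                lam=rng.uniform(0, 1), w=rng.uniform(0, 1),
                pi=rng.normal(0, 2),
            )
            s = HybridState.initial()
            s.q2 = rng.uniform(0, 1, (2, 2))
            s.q1mf = rng.uniform(0, 1, 2)
            s.prev_c1 = int(rng.integers(2))
            assert stage1_probs(s, p, TransitionModel()).sum() == pytest.approx(1.0)
            assert stage2_probs(s, p, 0).sum() == pytest.approx(1.0)

    def test_relabeling_boats_and_islands_preserves_nll(self):
        """The model sees option identities: a consistent relabeling of
        boats and islands (which leaves the symmetric transition matrix
        unchanged) must not change the likelihood."""
        p = RLParams(alpha1=0.4, alpha2=0.5, beta1=4.0, beta2=3.0,
                     lam=0.5, w=0.6, pi=0.2)
        walk = gaussian_walk(80, seed=11)
        trials = simulate_agent(p, walk, seed=12)
        relabelled = trials.copy()
        relabelled["c1"] = 1 - relabelled["c1"]
        relabelled["s2"] = 1 - relabelled["s2"]
        # island swap also swaps which walk column fed each monster, but
        # rewards are data here, so the likelihood is unchanged
        assert negloglik(p, relabelled) == pytest.approx(negloglik(p, trials), abs=1e-10)

    def test_invalid_trial_index_reported(self):
        with pytest.raises(DataError, match="index 1"):
            negloglik(RLParams(), [(0, 0, 0, 1), (0, 3, 0, 1)])


def test_generative_likelihood_self_consistency():
    """Averaged over datasets, the true parameters beat perturbed ones."""
    true = RLParams(alpha1=0.5, alpha2=0.5, beta1=6.0, beta2=6.0,
                    lam=0.5, w=0.7, pi=0.2)
    perturbed = RLParams(alpha1=0.9, alpha2=0.1, beta1=1.0, beta2=12.0,
                         lam=0.1, w=0.1, pi=-0.5)
    walk = gaussian_walk(201, seed=21)
    nll_true, nll_pert = [], []
    for d in range(15):
        trials = simulate_agent(true, walk, seed=100 + d)
        nll_true.append(negloglik(true, trials))
        nll_pert.append(negloglik(perturbed, trials))
    assert np.mean(nll_true) < np.mean(nll_pert)


def test_simulated_transitions_follow_structure():
    p = RLParams()
    walk = gaussian_walk(400, seed=31)
    trials = simulate_agent(p, walk, TransitionModel(), seed=32)
    common = (trials["s2"] == trials["c1"]).mean()
    assert common == pytest.approx(0.7, abs=0.07)
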