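"""Bayesian posterior, roulette selection, inverse-Bayesian replacement."""

import numpy as np
import pytest
from scipy import stats

from bibswarm.inference import (
    AgentState,
    Belief,
    DataWindow,
    SwarmBeliefs,
    apply_inverse_bayes,
    bayes_posterior,
    default_belief,
    inference_step,
    inference_update,
    roulette_select,
    select_inverse_target,
    window_probability,
)


class TestBayesPosterior:
    def test_uninformative_likelihood_keeps_prior(self):
        prior = np.array([0.25, 0.25, 0.25, 0.25])
        lik = np.full((4, 4), 0.25)
        post = bayes_posterior(Belief(prior, lik), d=2)
        assert post == pytest.approx(prior)

    def test_hand_computed_posterior(self):
        # uniform prior, likelihood column P(d=0|h) = (0.7, 0.1, 0.1, 0.1):
        # normalizer 0.25, posterior equals the column
        post = bayes_posterior(default_belief(), d=0)
        assert post == pytest.approx([0.7, 0.1, 0.1, 0.1])

    def test_degenerate_prior_absorbs(self):
        prior = np.array([1.0, 0.0, 0.0, 0.0])
        post = bayes_posterior(Belief(prior, default_belief().likelihood), d=3)
        assert post == pytest.approx(prior)

    def test_zero_normalizer_passes_prior_through(self):
        prior = np.full(4, 0.25)
        lik = default_belief().likelihood.copy()
        lik[:, 1] = 0.0
        lik /= lik.sum(axis=1, keepdims=True)
        post = bayes_posterior(Belief(prior, lik), d=1)
        assert post == pytest.approx(prior)

    def test_matches_naive_four_term_computation(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            prior = rng.dirichlet(np.ones(4))
            lik = rng.dirichlet(np.ones(4), size=4)
            d = rng.integers(0, 4)
            post = bayes_posterior(Belief(prior, lik), d)
            z = sum(lik[h, d] * prior[h] for h in range(4))
            naive = np.array([lik[h, d] * prior[h] / z for h in range(4)])
            assert post == pytest.approx(naive, abs=1e-12)
            assert post.sum() == pytest.approx(1.0, abs=1e-9)


class TestRoulette:
    def test_min_rule_example(self):
        # cumulative (0.2, 0.3, 0.7, 1.0): r=0.5 lands in index 2
        assert roulette_select(np.array([0.2, 0.1, 0.4, 0.3]), 0.5) == 2

    def test_degenerate_weights(self):
        assert roulette_select(np.array([1.0, 0.0, 0.0, 0.0]), 0.7) == 0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            roulette_select(np.zeros(4), 0.5)

    def test_empirical_frequencies_chi_square(self):
        w = np.array([0.2, 0.1, 0.4, 0.3])
        rng = np.random.default_rng(77)
        draws = [roulette_select(w, rng.random()) for _ in range(100_000)]
        counts = np.bincount(draws, minlength=4)
        p = stats.chisquare(counts, w * 100_000).pvalue
        assert p > 0.01


class TestInverseTarget:
    def test_cumulative_regions(self):
        # posterior (0.2, 0.1, 0.4, 0.3) -> EP = (0.8, 1.7, 2.3, 3.0)
        post = np.array([0.2, 0.1, 0.4, 0.3])
        assert select_inverse_target(post, 1.0) == 1
        assert select_inverse_target(post, 0.5) == 0
        assert select_inverse_target(post, 2.0) == 2
        assert select_inverse_target(post, 2.9) == 3

    def test_uniform_posterior_uniform_selection(self):
        rng = np.random.default_rng(5)
        post = np.full(4, 0.25)
        draws = [select_inverse_target(post, rng.random() * 3) for _ in range(40_000)]
        counts = np.bincount(draws, minlength=4)
        assert stats.chisquare(counts).pvalue > 0.01

    def test_low_probability_selected_most(self):
        post = np.array([0.7, 0.1, 0.1, 0.1])
        rng = np.random.default_rng(6)
        draws = [select_inverse_target(post, rng.random() * 3) for _ in range(30_000)]
        counts = np.bincount(draws, minlength=4)
        assert counts[0] < counts[1] and counts[0] < counts[2] and counts[0] < counts[3]
        p = stats.chisquare(counts, (1 - post) / 3 * 30_000).pvalue
        assert p > 0.01


class TestWindow:
    def test_worked_frequency_example(self):
        w = DataWindow(4)
        for s in (0, 0, 2, 1):
            w.push(s)
        assert window_probability(w) == pytest.approx([0.5, 0.25, 0.25, 0.0])

    def test_single_symbol(self):
        w = DataWindow(5)
        for s in (2, 2, 2):
            w.push(s)
        assert window_probability(w) == pytest.approx([0, 0, 1, 0])

    def test_warmup_uses_current_length(self):
        w = DataWindow(40)
        w.push(3)
        assert window_probability(w) == pytest.approx([0, 0, 0, 1])

    def test_fifo_eviction(self):
        w = DataWindow(2)
        for s in (0, 1, 2):
            w.push(s)
        assert w.symbols() == [1, 2]

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            window_probability(DataWindow(3))

    def test_matches_brute_force_counting(self):
        rng = np.random.default_rng(8)
        w = DataWindow(40)
        syms = rng.integers(0, 4, size=40)
        for s in syms:
            w.push(int(s))
        expect = [np.sum(syms == d) / 40 for d in range(4)]
        assert window_probability(w) == pytest.approx(expect)


class TestInverseBayes:
    def test_row_replacement(self):
        b = default_belief()
        wp = np.array([0.5, 0.25, 0.25, 0.0])
        out = apply_inverse_bayes(b, f=1, wp=wp)
        assert out.likelihood[1] == pytest.approx(wp)
        for row in (0, 2, 3):
            assert out.likelihood[row] == pytest.approx(b.likelihood[row])
        assert out.prior == pytest.approx(b.prior)

    def test_idempotent_on_equal_row(self):
        b = default_belief()
        out = apply_inverse_bayes(b, f=2, wp=b.likelihood[2].copy())
        assert out.likelihood == pytest.approx(b.likelihood)

    def test_unnormalized_wp_rejected(self):
        with pytest.raises(ValueError):
            apply_inverse_bayes(default_belief(), 0, np.array([0.5, 0.5, 0.5, 0.0]))


def make_agent(m=10):
    return AgentState(
        pos=np.zeros(2),
        prev_pos=np.array([-5.0, 0.0]),
        d=0,
        h=0,
        belief=default_belief(),
        window=DataWindow(m),
    )


class TestInferenceStep:
    def test_bo_likelihood_frozen(self):
        rng = np.random.default_rng(3)
        agent = make_agent()
        before = agent.belief.likelihood.copy()
        for _ in range(200):
            inference_step(agent, "BO", rng)
        assert np.array_equal(agent.belief.likelihood, before)

    def test_bib_all_zero_window_creates_degenerate_row(self):
        rng = np.random.default_rng(4)
        agent = make_agent(m=4)
        agent.d = 0
        for _ in range(4):
            agent.d = 0
            inference_step(agent, "BIB", rng)
        # after four pushes of 0 the window is pure, so some row is (1,0,0,0)
        assert any(
            np.allclose(agent.belief.likelihood[f], [1, 0, 0, 0]) for f in range(4)
        )

    @pytest.mark.parametrize("mode", ["BO", "BIB"])
    def test_normalization_preserved_over_long_runs(self, mode):
        rng = np.random.default_rng(5)
        agent = make_agent()
        for _ in range(10_000):
            inference_step(agent, mode, rng)
            assert abs(agent.belief.prior.sum() - 1.0) < 1e-9
            assert np.max(np.abs(agent.belief.likelihood.sum(axis=1) - 1.0)) < 1e-9
            assert agent.d in range(4) and agent.h in range(4)


class _QueueRng:
    """Deterministic stand-in feeding prescribed uniforms."""

    def __init__(self, values):
        self.values = list(values)

    def random(self, n=None):
        if n is None:
            return self.values.pop(0)
        return np.array([self.values.pop(0) for _ in range(n)])


class TestVectorizedAgreement:
    @pytest.mark.parametrize("mode", ["BO", "BIB"])
    def test_vectorized_matches_per_agent_path(self, mode):
        n, m = 16, 6
        rng = np.random.default_rng(21)
        beliefs = SwarmBeliefs(n, m)
        beliefs.prior = rng.dirichlet(np.ones(4), size=n)
        beliefs.likelihood = rng.dirichlet(np.ones(4), size=(n, 4))
        d = rng.integers(0, 4, size=n)
        r_f = rng.random(n)
        r_h = rng.random(n)
        r_d = rng.random(n)

        agents = []
        for k in range(n):
            a = make_agent(m)
            a.belief = Belief(beliefs.prior[k].copy(), beliefs.likelihood[k].copy())
            a.d = int(d[k])
            agents.append(a)

        vec_rng = _QueueRng(
            (list(r_f) if mode == "BIB" else []) + list(r_h) + list(r_d)
        )
        h_new, d_new = inference_update(beliefs, d, mode, vec_rng)

        for k, a in enumerate(agents):
            qs = ([r_f[k]] if mode == "BIB" else []) + [r_h[k], r_d[k]]
            inference_step(a, mode, _QueueRng(qs))
            assert a.h == h_new[k]
            assert a.d == d_new[k]
            assert a.belief.prior == pytest.approx(beliefs.prior[k])
            assert a.belief.likelihood == pytest.approx(beliefs.likelihood[k])
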