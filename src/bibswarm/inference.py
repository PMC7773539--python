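"""Per-agent decision machinery: Bayesian and inverse-Bayesian inference.

Each agent holds a prior ``P(h)`` over four hypotheses and a 4x4
row-stochastic likelihood table ``P(d|h)``.  One inference step:

1. **Bayes**: the prior is replaced by the posterior ``P(h|d)`` given the
   agent's current data symbol ``d``.
2. **Inverse Bayes** (BIB only): a target hypothesis ``f`` is sampled with
   probability proportional to ``1 - P(h)`` — unlikely hypotheses are
   preferentially rewritten — and its likelihood row is replaced wholesale
   by the empirical frequency of the agent's last ``m`` data symbols.
3. The next hypothesis ``h`` is sampled from the posterior by roulette
   wheel, and the next data symbol ``d`` from the likelihood row of ``h``.

The data symbol feeds back into the movement rule as the angular offset
``d * pi/2``, closing the perception-action loop.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Belief",
    "DataWindow",
    "AgentState",
    "default_belief",
    "bayes_posterior",
    "roulette_select",
    "select_inverse_target",
    "window_probability",
    "apply_inverse_bayes",
    "inference_step",
]

N_SYMBOLS = 4


@dataclass
class Belief:
    """Prior over hypotheses and row-stochastic likelihood table ``P(d|h)``.

    ``likelihood[h, d]`` is the probability of data ``d`` under hypothesis
    ``h``; every row sums to 1.
    """

    prior: np.ndarray
    likelihood: np.ndarray

    def validate(self, atol: float = 1e-9) -> None:
        prior = np.asarray(self.prior, float)
        lik = np.asarray(self.likelihood, float)
        if prior.shape != (N_SYMBOLS,) or lik.shape != (N_SYMBOLS, N_SYMBOLS):
            raise ValueError("belief must be a 4-vector prior and a 4x4 likelihood")
        if np.any(prior < 0) or np.any(lik < 0):
            raise ValueError("negative probabilities")
        if abs(prior.sum() - 1.0) > atol:
            raise ValueError("prior does not sum to 1")
        if np.max(np.abs(lik.sum(axis=1) - 1.0)) > atol:
            raise ValueError("likelihood rows must sum to 1")

    def copy(self) -> "Belief":
        return Belief(np.array(self.prior, float), np.array(self.likelihood, float))


class DataWindow:
    """FIFO buffer of the most recent <= ``m`` data symbols."""

    def __init__(self, m: int):
        if m < 1:
            raise ValueError("window size m >= 1 required")
        self.m = m
        self._buf: deque[int] = deque(maxlen=m)

    def push(self, d: int) -> None:
        if d not in range(N_SYMBOLS):
            raise ValueError("symbol out of range")
        self._buf.append(int(d))

    def __len__(self) -> int:
        return len(self._buf)

    def symbols(self) -> list[int]:
        return list(self._buf)


@dataclass
class AgentState:
    """Full per-agent state: kinematics plus belief."""

    pos: np.ndarray
    prev_pos: np.ndarray
    d: int
    h: int
    belief: Belief
    window: DataWindow = field(default_factory=lambda: DataWindow(10))


def default_belief() -> Belief:
    """Initial belief: uniform prior; ``P(d|h) = 0.7`` if ``d == h`` else 0.1."""
    prior = np.full(N_SYMBOLS, 0.25)
    lik = np.full((N_SYMBOLS, N_SYMBOLS), 0.1)
    np.fill_diagonal(lik, 0.7)
    return Belief(prior, lik)


def bayes_posterior(belief: Belief, d: int, floor: float = 0.0) -> np.ndarray:
    """Posterior ``P(h|d) = P(d|h) P(h) / sum_h' P(d|h') P(h')``.

    A zero normalizer (possible once inverse-Bayes writes zero entries into
    the likelihood) returns the prior unchanged: an impossible observation
    carries no information.  ``floor``, if positive, is added to the
    likelihood column before normalizing as an optional regularizer.
    """
    if d not in range(N_SYMBOLS):
        raise ValueError("d must be in {0,1,2,3}")
    prior = np.asarray(belief.prior, float)
    col = np.asarray(belief.likelihood, float)[:, d]
    if floor > 0:
        col = col + floor
    num = col * prior
    z = num.sum()
    if z <= 0.0:
        return prior.copy()
    return num / z


def roulette_select(weights: np.ndarray, r: float) -> int:
    """Smallest index ``i`` with ``r <= cumsum(weights)[i]``.

    With ``r ~ U[0, sum(weights)]`` index ``i`` is selected with
    probability ``weights[i] / sum(weights)``.
    """
    weights = np.asarray(weights, float)
    if np.any(weights < 0):
        raise ValueError("negative weights")
    total = weights.sum()
    if total <= 0.0:
        raise ValueError("all-zero weights")
    cum = np.cumsum(weights)
    idx = int(np.searchsorted(cum, r, side="left"))
    return min(idx, len(weights) - 1)


def select_inverse_target(posterior: np.ndarray, r: float) -> int:
    """Inverse-roulette: sample ``f`` with probability ``(1 - P(f)) / 3``.

    The cumulative weight ``EP(h) = sum_{h' <= h} (1 - P(h'))`` reaches 3
    for a normalized 4-vector; ``f`` is the smallest ``h`` with
    ``r <= EP(h)``, so low-probability hypotheses occupy the widest
    regions and are rewritten most often.
    """
    posterior = np.asarray(posterior, float)
    return roulette_select(1.0 - posterior, r)


def window_probability(window: DataWindow) -> np.ndarray:
    """Empirical symbol frequencies of the window: ``P(d) = #{d in buffer} / len``.

    Before the buffer has filled, the current length is the denominator,
    so the result always sums to 1.  Empty windows are rejected.
    """
    n = len(window)
    if n == 0:
        raise ValueError("empty data window")
    counts = np.bincount(window.symbols(), minlength=N_SYMBOLS)
    return counts / n


def apply_inverse_bayes(belief: Belief, f: int, wp: np.ndarray) -> Belief:
    """Replace likelihood row ``f`` with the window frequencies ``wp``.

    The prior and all other rows are untouched; row-stochasticity is
    preserved because ``wp`` is normalized.
    """
    wp = np.asarray(wp, float)
    if abs(wp.sum() - 1.0) > 1e-9:
        raise ValueError("window probability must sum to 1")
    out = belief.copy()
    out.likelihood[f] = wp
    return out


def inference_step(agent: AgentState, mode: str, rng: np.random.Generator) -> AgentState:
    """One full inference update (in place); returns the agent.

    Order: Bayes posterior -> (BIB) window push, inverse-Bayes row
    replacement with the target drawn from the *posterior* -> sample the
    next hypothesis from the posterior -> sample the next datum from that
    hypothesis's likelihood row.  Draw order per agent: inverse-target r
    (BIB only), hypothesis r, datum r.
    """
    if mode not in ("BO", "BIB"):
        raise ValueError("mode must be 'BO' or 'BIB'")
    posterior = bayes_posterior(agent.belief, agent.d)
    agent.belief.prior = posterior
    if mode == "BIB":
        agent.window.push(agent.d)
        wp = window_probability(agent.window)
        f = select_inverse_target(posterior, rng.random() * (N_SYMBOLS - 1))
        agent.belief = apply_inverse_bayes(agent.belief, f, wp)
    agent.h = roulette_select(posterior, rng.random())
    row = agent.belief.likelihood[agent.h]
    agent.d = roulette_select(row, rng.random() * row.sum())
    return agent


# ---------------------------------------------------------------------------
# vectorized counterparts used by the engine


class SwarmBeliefs:
    """Array-of-structs belief state for N agents (engine internal)."""

    def __init__(self, n: int, m: int):
        self.n = n
        self.m = m
        self.prior = np.full((n, N_SYMBOLS), 0.25)
        self.likelihood = np.broadcast_to(
            default_belief().likelihood, (n, N_SYMBOLS, N_SYMBOLS)
        ).copy()
        self.window = np.zeros((n, m), dtype=np.int8)
        self.win_len = np.zeros(n, dtype=np.int64)
        self.win_ptr = np.zeros(n, dtype=np.int64)

    def push_window(self, d: np.ndarray) -> None:
        self.window[np.arange(self.n), self.win_ptr] = d
        self.win_ptr = (self.win_ptr + 1) % self.m
        np.minimum(self.win_len + 1, self.m, out=self.win_len)

    def window_probability(self) -> np.ndarray:
        wp = np.zeros((self.n, N_SYMBOLS))
        rows = np.repeat(np.arange(self.n), np.minimum(self.win_len, self.m))
        mask = np.arange(self.m)[None, :] < self.win_len[:, None]
        np.add.at(wp, (rows, self.window[mask]), 1.0)
        return wp / self.win_len[:, None]


def inference_update(
    beliefs: SwarmBeliefs,
    d: np.ndarray,
    mode: str,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`inference_step` over all agents.

    Returns the new ``(h, d)`` arrays.  Per step the generator is consumed
    in a fixed order — inverse-target uniforms (BIB), hypothesis uniforms,
    datum uniforms — each in agent-index order.
    """
    n = beliefs.n
    idx = np.arange(n)
    col = beliefs.likelihood[idx, :, d]  # P(d_k | h) for each agent
    num = col * beliefs.prior
    z = num.sum(axis=1)
    ok = z > 0.0
    posterior = np.where(ok[:, None], num / np.where(ok, z, 1.0)[:, None], beliefs.prior)
    beliefs.prior = posterior

    if mode == "BIB":
        beliefs.push_window(d)
        wp = beliefs.window_probability()
        r_f = rng.random(n) * (N_SYMBOLS - 1)
        cum_inv = np.cumsum(1.0 - posterior, axis=1)
        f = _first_reached(cum_inv, r_f)
        beliefs.likelihood[idx, f] = wp

    r_h = rng.random(n)
    cum_h = np.cumsum(posterior, axis=1)
    h_new = _first_reached(cum_h, r_h)

    rows = beliefs.likelihood[idx, h_new]
    r_d = rng.random(n) * rows.sum(axis=1)
    cum_d = np.cumsum(rows, axis=1)
    d_new = _first_reached(cum_d, r_d)
    return h_new, d_new


def _first_reached(cum: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Per row: smallest index with ``r <= cum`` (cum is nondecreasing)."""
    hit = r[:, None] <= cum
    out = hit.argmax(axis=1)
    # rows where float rounding left every cum below r: take the last index
    out[~hit.any(axis=1)] = cum.shape[1] - 1
    return out
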