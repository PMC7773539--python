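"""Time-stepping: initialize a swarm and advance all agents synchronously.

Per recorded step ``t -> t+1``:

1. every agent's heading is computed from the configuration at ``t`` and
   ``t-1`` (neighborhoods on the ``t-1`` positions, displacements
   ``pos^t - pos^{t-1}``);
2. every agent moves a distance ``V`` along its perturbed heading offset
   by ``d * pi/2``;
3. (BO/BIB) every agent runs one inference step, producing the symbols
   used at ``t+1``.

All updates are synchronous: headings are functions of the previous
configuration only.  Positions are stored unwrapped even under a periodic
boundary; wrapping only enters distance computations, so step geometry is
never corrupted by wrap jumps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import SwarmConfig
from .core import headings_vectorized, move_vectorized
from .inference import SwarmBeliefs, inference_update

__all__ = ["Trajectory", "init_swarm", "simulate"]


@dataclass
class Trajectory:
    """Recorded run: unwrapped positions and symbols at ``t = 1 .. T``.

    ``xs``/``ys`` are ``(T, N)`` float arrays; ``d``/``h`` are ``(T, N)``
    int8 arrays (zero for the plain SPP, which carries no belief).
    """

    xs: np.ndarray
    ys: np.ndarray
    d: np.ndarray
    h: np.ndarray
    config: SwarmConfig

    @property
    def T(self) -> int:
        return self.xs.shape[0]

    @property
    def N(self) -> int:
        return self.xs.shape[1]

    def positions(self, t_index: int) -> np.ndarray:
        """(N, 2) positions at zero-based time index."""
        return np.column_stack([self.xs[t_index], self.ys[t_index]])

    def track(self, k: int) -> np.ndarray:
        """(T, 2) unwrapped track of agent ``k``."""
        return np.column_stack([self.xs[:, k], self.ys[:, k]])


@dataclass
class _State:
    pos: np.ndarray
    prev_pos: np.ndarray
    theta: np.ndarray
    d: np.ndarray
    h: np.ndarray
    beliefs: SwarmBeliefs | None


def init_swarm(config: SwarmConfig, rng: np.random.Generator) -> _State:
    """Place agents, bootstrap headings, and initialize beliefs.

    Placement is uniform over the periodic box or over a central square of
    side ``init_side``.  Each agent starts with a heading
    ``theta0 ~ U[0, 2pi)`` and a virtual previous position one step of
    length ``V`` behind, which makes the first mean-heading computation
    well defined.  Beliefs start from the uniform prior and the
    0.7-diagonal likelihood; the first datum is uniform over {0..3} and
    the first hypothesis is drawn from the prior.
    """
    n = config.N
    if config.init == "uniform_box":
        L = config.boundary.L
        pos = rng.uniform(0.0, L, size=(n, 2))
    else:
        c = config.init_side
        pos = rng.uniform(-c / 2.0, c / 2.0, size=(n, 2))
    theta0 = rng.uniform(0.0, 2.0 * np.pi, size=n)
    prev = pos - config.V * np.column_stack([np.cos(theta0), np.sin(theta0)])

    if config.model == "SPP":
        d = np.zeros(n, dtype=np.int64)
        h = np.zeros(n, dtype=np.int64)
        beliefs = None
    else:
        beliefs = SwarmBeliefs(n, config.m)
        d = rng.integers(0, 4, size=n)
        r_h = rng.random(n)
        cum = np.cumsum(beliefs.prior, axis=1)
        h = (r_h[:, None] <= cum).argmax(axis=1)
    return _State(pos=pos, prev_pos=prev, theta=theta0, d=d, h=h, beliefs=beliefs)


def simulate(config: SwarmConfig) -> Trajectory:
    """Run a full simulation; a pure function of ``(config, config.seed)``."""
    rng = np.random.default_rng(config.seed)
    state = init_swarm(config, rng)
    T, n = config.steps, config.N

    xs = np.empty((T, n))
    ys = np.empty((T, n))
    ds = np.empty((T, n), dtype=np.int8)
    hs = np.empty((T, n), dtype=np.int8)
    xs[0], ys[0] = state.pos[:, 0], state.pos[:, 1]
    ds[0], hs[0] = state.d, state.h

    for t in range(1, T):
        theta = headings_vectorized(
            state.pos, state.prev_pos, config.R, config.boundary, state.theta
        )
        new_pos = move_vectorized(state.pos, theta, state.d, config.epsilon, config.V, rng)
        state.prev_pos = state.pos
        state.pos = new_pos
        state.theta = theta
        if config.model != "SPP":
            h_new, d_new = inference_update(state.beliefs, state.d, config.model, rng)
            state.h = h_new
            state.d = d_new
        xs[t], ys[t] = state.pos[:, 0], state.pos[:, 1]
        ds[t], hs[t] = state.d, state.h

    return Trajectory(xs=xs, ys=ys, d=ds, h=hs, config=config)
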