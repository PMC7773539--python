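"""Tornado, splash and translation behavior indexes.

Per time step, three non-exclusive counts over agents:

* **tornado** — windowed mean turning angle in ``(alpha_tor, alpha_tor_hi)``:
  the agent is circling;
* **splash** — nearest-neighbor distance grew by more than ``r_spl`` over
  the last ``T_spl`` steps: the agent is being flung away from the group;
* **translation** — windowed mean turning angle below ``alpha_trans``: the
  agent moves straight.

The count series, their tornado/translation and splash/translation ratio
summaries, and the nonparametric comparisons between model variants are
the phase-classification readout of a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial import cKDTree

from .config import Boundary
from .engine import Trajectory
from .steps import bending_angles

__all__ = [
    "IndexParams",
    "mean_turn",
    "tornado_count",
    "splash_count",
    "translation_count",
    "index_series",
    "ratio_summary",
    "compare_models",
]


@dataclass(frozen=True)
class IndexParams:
    """Thresholds of the three indexes.

    ``alpha_tor`` / ``alpha_tor_hi`` bracket the tornado band of the mean
    turning angle; ``alpha_trans`` bounds the translation band; ``r_spl``
    is the nearest-neighbor growth threshold over ``T_spl`` steps; ``W``
    is the trailing window over which turning angles are averaged.
    """

    alpha_tor: float = np.pi / 30.0
    alpha_tor_hi: float = np.pi / 10.0
    alpha_trans: float = np.pi / 30.0
    r_spl: float = 8.0
    T_spl: int = 10
    W: int = 10

    def __post_init__(self) -> None:
        if not (0 < self.alpha_tor < self.alpha_tor_hi):
            raise ValueError("need 0 < alpha_tor < alpha_tor_hi")
        if not self.r_spl > 0:
            raise ValueError("r_spl > 0 required")
        if self.W < 1 or self.T_spl < 1:
            raise ValueError("W >= 1 and T_spl >= 1 required")


def mean_turn(track: np.ndarray, t: int, W: int, V: float) -> float:
    """Mean bending angle over the trailing window ending at time ``t``.

    ``t`` is a one-based time step; the window covers the turns at
    ``t-W+1 .. t``, so ``t >= W + 2`` is required (turns exist from
    ``t = 3``).  Raises when the history is insufficient; callers exclude
    such agents from that step's counts.
    """
    if t < W + 2:
        raise ValueError("insufficient history for the turning window")
    alphas = bending_angles(np.asarray(track, float)[t - W - 2 : t], V)
    return float(alphas.mean())


def _mean_turn_matrix(traj: Trajectory, W: int) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean turn for all agents and admissible times.

    Returns ``(times, M)`` with ``times`` one-based (from ``W+2``) and
    ``M`` of shape ``(len(times), N)``.
    """
    V = traj.config.V
    T = traj.T
    dx = np.diff(traj.xs, axis=0)
    dy = np.diff(traj.ys, axis=0)
    dots = (dx[:-1] * dx[1:] + dy[:-1] * dy[1:]) / (V * V)
    alphas = np.arccos(np.clip(dots, -1.0, 1.0))  # (T-2, N); row i = turn at t=i+2
    c = np.cumsum(alphas, axis=0)
    c = np.vstack([np.zeros((1, traj.N)), c])
    means = (c[W:] - c[:-W]) / W  # window ending at turn row W-1+i -> t = W+1+i
    times = np.arange(W + 2, T + 1)
    return times, means[: len(times)]


def tornado_count(traj: Trajectory, t: int, params: IndexParams) -> int:
    """Agents whose mean turn lies strictly inside the tornado band at ``t``."""
    times, M = _mean_turn_matrix(traj, params.W)
    row = M[np.searchsorted(times, t)]
    return int(np.sum((row > params.alpha_tor) & (row < params.alpha_tor_hi)))


def translation_count(traj: Trajectory, t: int, params: IndexParams) -> int:
    """Agents whose mean turn is below ``alpha_trans`` at ``t``."""
    times, M = _mean_turn_matrix(traj, params.W)
    row = M[np.searchsorted(times, t)]
    return int(np.sum(row < params.alpha_trans))


def nearest_neighbor_distances(positions: np.ndarray, boundary: Boundary) -> np.ndarray:
    """Distance of each agent to its nearest other agent (minimum-image)."""
    positions = np.asarray(positions, float)
    n = len(positions)
    if n < 2:
        return np.full(n, np.inf)
    if boundary.periodic:
        L = boundary.L
        wrapped = np.mod(positions, L)
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
        dist, _ = tree.query(wrapped, k=2)
    else:
        tree = cKDTree(positions)
        dist, _ = tree.query(positions, k=2)
    return dist[:, 1]


def splash_count(traj: Trajectory, t: int, params: IndexParams) -> int:
    """Agents whose nearest-neighbor distance grew by more than ``r_spl``
    between ``t - T_spl`` and ``t``.  Needs ``t > T_spl``; with a single
    agent the count is 0.
    """
    if t <= params.T_spl:
        raise ValueError("insufficient history for the splash interval")
    if traj.N < 2:
        return 0
    b = traj.config.boundary
    now = nearest_neighbor_distances(traj.positions(t - 1), b)
    then = nearest_neighbor_distances(traj.positions(t - 1 - params.T_spl), b)
    return int(np.sum(now - then > params.r_spl))


def index_series(traj: Trajectory, params: IndexParams | None = None) -> pd.DataFrame:
    """The three counts at every admissible time step.

    Admissible times start at ``max(W + 2, T_spl + 1)`` so that all three
    indexes have full history.  Returns columns ``t, tornado, splash,
    translation``.
    """
    params = params or IndexParams()
    t0 = max(params.W + 2, params.T_spl + 1)
    if traj.T < t0:
        raise ValueError("trajectory shorter than the index warm-up")
    times, M = _mean_turn_matrix(traj, params.W)
    keep = times >= t0
    times = times[keep]
    M = M[keep]
    tor = np.sum((M > params.alpha_tor) & (M < params.alpha_tor_hi), axis=1)
    trs = np.sum(M < params.alpha_trans, axis=1)

    b = traj.config.boundary
    if traj.N < 2:
        spl = np.zeros(len(times), dtype=int)
    else:
        nnd = np.stack(
            [nearest_neighbor_distances(traj.positions(i), b) for i in range(traj.T)]
        )
        growth = nnd[times - 1] - nnd[times - 1 - params.T_spl]
        spl = np.sum(growth > params.r_spl, axis=1)
    return pd.DataFrame(
        {"t": times, "tornado": tor, "splash": spl, "translation": trs}
    )


def ratio_summary(series: pd.DataFrame) -> dict:
    """Six-number summaries of the tornado/translation and
    splash/translation ratio series.

    Time steps with a zero translation count are skipped (their number is
    reported as ``skipped``).  Quartiles use the linear-interpolation
    convention.  Raises if the translation count is zero everywhere.
    """
    if len(series) == 0:
        raise ValueError("empty index series")
    ok = series["translation"].to_numpy() > 0
    if not ok.any():
        raise ValueError("translation count is zero at every time step")
    tor = series["tornado"].to_numpy()[ok] / series["translation"].to_numpy()[ok]
    spl = series["splash"].to_numpy()[ok] / series["translation"].to_numpy()[ok]

    def six(x: np.ndarray) -> dict:
        q1, med, q3 = np.quantile(x, [0.25, 0.5, 0.75])
        return {
            "Min": float(x.min()),
            "1st Qu": float(q1),
            "Median": float(med),
            "Mean": float(x.mean()),
            "3rd Qu": float(q3),
            "Max": float(x.max()),
        }

    return {
        "tornado_translation": six(tor),
        "splash_translation": six(spl),
        "skipped": int((~ok).sum()),
    }


def ratio_series(series: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-step ratio vectors (tornado/trans, splash/trans), zero-translation steps skipped."""
    ok = series["translation"].to_numpy() > 0
    tr = series["translation"].to_numpy()[ok].astype(float)
    return series["tornado"].to_numpy()[ok] / tr, series["splash"].to_numpy()[ok] / tr


def compare_models(ratios_a: np.ndarray, ratios_b: np.ndarray, *groups) -> dict:
    """Nonparametric comparison of two (or more) ratio series.

    Shapiro-Wilk normality p per series, the two-sided Wilcoxon rank-sum
    p for A vs B, and — when extra groups are supplied — the
    Kruskal-Wallis p across all of them.  Degenerate all-tied input is
    reported as not computable rather than raising.
    """
    a = np.asarray(ratios_a, float)
    b = np.asarray(ratios_b, float)
    if len(a) < 3 or len(b) < 3:
        raise ValueError("need at least 3 observations per series")

    def shapiro_p(x: np.ndarray) -> float | None:
        if np.ptp(x) == 0:
            return None
        return float(stats.shapiro(x[:5000]).pvalue)

    report = {
        "shapiro_p_a": shapiro_p(a),
        "shapiro_p_b": shapiro_p(b),
    }
    if np.ptp(np.concatenate([a, b])) == 0:
        report["wilcoxon_p"] = None
    else:
        report["wilcoxon_p"] = float(stats.ranksums(a, b).pvalue)
    if groups:
        allg = [a, b, *[np.asarray(g, float) for g in groups]]
        if np.ptp(np.concatenate(allg)) == 0:
            report["kruskal_p"] = None
        else:
            report["kruskal_p"] = float(stats.kruskal(*allg).pvalue)
    return report
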