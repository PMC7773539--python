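"""Kinematics of the self-propelled particles.

Neighborhoods of radius ``R`` (minimum-image under a periodic boundary),
the mean-heading rule, and the constant-speed movement rule.  Functions
here operate on raw coordinate arrays; the time-stepping lives in
:mod:`bibswarm.engine`.

The alignment rule: agent ``k`` takes the angle of the *summed* displacement
vector of all neighbors (itself included) over the last step,

    theta_k = atan2( sum_j (y_j^t - y_j^{t-1}), sum_j (x_j^t - x_j^{t-1}) ),

and then moves a distance ``V`` along ``theta_k + s*u + d*pi/2`` where
``u ~ U[0, epsilon]``, ``s`` is a fair sign, and ``d`` in {0,1,2,3} is the
agent's current data symbol (0 = comply with the flock, 2 = flee in the
reverse direction).
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .config import Boundary

__all__ = [
    "minimum_image",
    "neighbors_of",
    "neighbor_pairs",
    "mean_heading",
    "move_agent",
]


def minimum_image(delta: np.ndarray, L: Optional[float]) -> np.ndarray:
    """Wrap coordinate differences into ``[-L/2, L/2)``; identity when ``L`` is None."""
    if L is None:
        return delta
    return delta - L * np.round(delta / L)


def _check_positions(positions: np.ndarray) -> np.ndarray:
    positions = np.asarray(positions, dtype=float)
    if positions.ndim != 2 or positions.shape[1] != 2:
        raise ValueError("positions must be an (N, 2) array")
    if not np.all(np.isfinite(positions)):
        raise ValueError("non-finite coordinates")
    return positions


def neighbors_of(k: int, positions: np.ndarray, R: float, boundary: Boundary) -> np.ndarray:
    """Indices of all agents within distance ``R`` of agent ``k``.

    Distances are minimum-image under a periodic boundary.  Agent ``k`` is
    always a member of its own neighborhood (distance 0), so the result is
    never empty.
    """
    positions = _check_positions(positions)
    if not R > 0:
        raise ValueError("R > 0 required")
    delta = minimum_image(positions - positions[k], boundary.L if boundary.periodic else None)
    d2 = np.einsum("ij,ij->i", delta, delta)
    return np.flatnonzero(d2 <= R * R)


def neighbor_pairs(positions: np.ndarray, R: float, boundary: Boundary) -> np.ndarray:
    """All unordered pairs ``(i, j)``, ``i < j``, within distance ``R``.

    Backed by a k-d tree (periodic boxes use the tree's toroidal metric),
    so the cost is near-linear in N for short-range R.  Results agree with
    the brute-force minimum-image scan.
    """
    positions = _check_positions(positions)
    if boundary.periodic:
        L = boundary.L
        wrapped = np.mod(positions, L)
        # guard against wrapped == L from float rounding
        wrapped[wrapped >= L] = 0.0
        tree = cKDTree(wrapped, boxsize=L)
    else:
        tree = cKDTree(positions)
    pairs = tree.query_pairs(R, output_type="ndarray")
    return pairs.reshape(-1, 2)


def mean_heading(
    nbrs: Sequence[int],
    positions_t: np.ndarray,
    positions_tm1: np.ndarray,
) -> tuple[float, bool]:
    """Angle of the summed neighbor displacement; ``(angle, defined)``.

    Returns ``defined=False`` when the summed displacement is the zero
    vector (the heading is then undefined and the caller keeps the
    previous one).
    """
    nbrs = np.asarray(nbrs, dtype=int)
    if nbrs.size == 0:
        raise ValueError("empty neighbor set (self-inclusion should prevent this)")
    disp = np.asarray(positions_t, float)[nbrs] - np.asarray(positions_tm1, float)[nbrs]
    sx, sy = disp.sum(axis=0)
    if sx == 0.0 and sy == 0.0:
        return 0.0, False
    return float(np.arctan2(sy, sx)), True


def move_agent(
    pos: np.ndarray,
    theta: float,
    d: int,
    epsilon: float,
    V: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """One movement step: ``pos + V * (cos phi, sin phi)``.

    ``phi = theta + s*u + d*pi/2`` with ``u ~ U[0, epsilon]`` and an
    independent fair sign ``s``; the displacement magnitude is exactly
    ``V`` up to float rounding.
    """
    if d not in (0, 1, 2, 3):
        raise ValueError("d must be in {0,1,2,3}")
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    u = rng.uniform(0.0, epsilon) if epsilon > 0 else 0.0
    s = 1.0 if rng.random() < 0.5 else -1.0
    phi = theta + s * u + d * (np.pi / 2.0)
    return np.asarray(pos, float) + V * np.array([np.cos(phi), np.sin(phi)])


def headings_vectorized(
    pos: np.ndarray,
    prev_pos: np.ndarray,
    R: float,
    boundary: Boundary,
    prev_theta: np.ndarray,
) -> np.ndarray:
    """Mean heading of every agent in one pass.

    Neighborhoods are evaluated on the previous configuration (the rule
    tests distances at ``t-1``); displacements are ``pos - prev_pos``.
    The alignment average excludes the agent's own displacement: feeding
    the agent's own d-rotated move back into its matched heading would
    make an isolated agent chase its own offset (a locked ``d=1`` agent
    would loop in a five-unit square forever) instead of holding course.
    Agents with no neighbors, or whose neighbors' displacements cancel
    exactly, keep ``prev_theta``.
    """
    disp = pos - prev_pos
    sums = np.zeros_like(disp)
    pairs = neighbor_pairs(prev_pos, R, boundary)
    if len(pairs):
        np.add.at(sums, pairs[:, 0], disp[pairs[:, 1]])
        np.add.at(sums, pairs[:, 1], disp[pairs[:, 0]])
    theta = np.arctan2(sums[:, 1], sums[:, 0])
    undefined = (sums[:, 0] == 0.0) & (sums[:, 1] == 0.0)
    if undefined.any():
        theta = np.where(undefined, prev_theta, theta)
    return theta


def move_vectorized(
    pos: np.ndarray,
    theta: np.ndarray,
    d: np.ndarray,
    epsilon: float,
    V: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Move all agents at once; same semantics as :func:`move_agent`.

    Draw order per step: one uniform magnitude array, then one sign array
    (agent-index order), so runs are reproducible bit-for-bit at a fixed
    seed.
    """
    n = len(pos)
    u = rng.uniform(0.0, epsilon, size=n) if epsilon > 0 else np.zeros(n)
    s = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    phi = theta + s * u + d * (np.pi / 2.0)
    step = np.empty_like(pos)
    step[:, 0] = np.cos(phi)
    step[:, 1] = np.sin(phi)
    return pos + V * step
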