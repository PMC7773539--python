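"""Step-length extraction by bending-angle segmentation.

A walk is cut into straight "steps" at bending points: positions where the
turning angle between successive displacements exceeds ``alpha_max``
(default ``2*pi/9`` = 40 degrees).  The step length ``D`` is the Euclidean
distance between consecutive bending points; the pooled distribution of
``D`` over all agents is the object the Levy-walk analysis fits.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = ["ALPHA_MAX_DEFAULT", "bending_angle", "bending_angles", "extract_steps", "pool_steps"]

ALPHA_MAX_DEFAULT = 2.0 * np.pi / 9.0


def bending_angle(p0, p1, p2, V: float) -> float:
    """Turning angle in ``[0, pi]`` at ``p1`` of the path ``p0 -> p1 -> p2``.

    ``arccos`` of the dot product of the two displacements divided by
    ``V**2``, the argument clamped to ``[-1, 1]`` against float rounding.
    Displacements of speed-V walkers always have magnitude V, so a zero
    displacement is rejected.
    """
    a = np.asarray(p1, float) - np.asarray(p0, float)
    b = np.asarray(p2, float) - np.asarray(p1, float)
    if not (np.any(a) and np.any(b)):
        raise ValueError("zero displacement has no bending angle")
    c = float(np.dot(a, b)) / (V * V)
    return float(np.arccos(np.clip(c, -1.0, 1.0)))


def bending_angles(track: np.ndarray, V: float) -> np.ndarray:
    """All turning angles of a ``(T, 2)`` track; length ``T - 2``."""
    track = np.asarray(track, float)
    disp = np.diff(track, axis=0)
    dots = np.einsum("ij,ij->i", disp[:-1], disp[1:]) / (V * V)
    return np.arccos(np.clip(dots, -1.0, 1.0))


def extract_steps(
    track: np.ndarray,
    alpha_max: float = ALPHA_MAX_DEFAULT,
    V: float = 5.0,
    emit_tail: bool = False,
) -> pd.DataFrame:
    """Step lengths of one unwrapped track.

    Scanning the turning angle at each interior position, a step
    terminates at the position *before* the first super-threshold turn
    (strict ``alpha > alpha_max``); its length is the straight-line
    distance from the previous bending point, which then advances.  The
    first bending point is the start of the track.  The trailing segment
    after the last bending point is incomplete and discarded unless
    ``emit_tail`` is set (kept only for sensitivity checks: emitting it
    biases the long-step count upward by one per agent).

    Returns a frame with columns ``length, start_t, end_t`` where times are
    zero-based track indices.
    """
    track = np.asarray(track, float)
    cols = {"length": float, "start_t": int, "end_t": int}
    if len(track) < 3:
        return pd.DataFrame({k: pd.Series(dtype=v) for k, v in cols.items()})
    alphas = bending_angles(track, V)  # alphas[i] is the turn at position i+1
    # a turn at position j (track index) ends a step at j; angle index j-1
    turn_pos = np.flatnonzero(alphas > alpha_max) + 1
    lengths, starts, ends = [], [], []
    prev = 0
    for j in turn_pos:
        d = float(np.hypot(*(track[j] - track[prev])))
        lengths.append(d)
        starts.append(prev)
        ends.append(int(j))
        prev = int(j)
    if emit_tail and prev < len(track) - 1:
        lengths.append(float(np.hypot(*(track[-1] - track[prev]))))
        starts.append(prev)
        ends.append(len(track) - 1)
    return pd.DataFrame({"length": lengths, "start_t": starts, "end_t": ends})


def pool_steps(
    traj: Trajectory,
    alpha_max: float = ALPHA_MAX_DEFAULT,
    emit_tail: bool = False,
) -> pd.DataFrame:
    """Concatenate per-agent step tables with provenance.

    Columns: ``agent, start_t, end_t, length``; times are one-based to
    match the trajectory's time axis.
    """
    V = traj.config.V
    frames = []
    for k in range(traj.N):
        f = extract_steps(traj.track(k), alpha_max=alpha_max, V=V, emit_tail=emit_tail)
        if len(f):
            f = f.assign(agent=k, start_t=f["start_t"] + 1, end_t=f["end_t"] + 1)
            frames.append(f)
    if not frames:
        return pd.DataFrame(
            {
                "agent": pd.Series(dtype=int),
                "start_t": pd.Series(dtype=int),
                "end_t": pd.Series(dtype=int),
                "length": pd.Series(dtype=float),
            }
        )
    out = pd.concat(frames, ignore_index=True)
    return out[["agent", "start_t", "end_t", "length"]]
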