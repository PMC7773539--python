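"""Trajectory CSV round-trip and run manifests.

Trajectory files are plain CSV with header ``t,agent,x,y,d,h`` preceded by
a commented metadata block (``# key: value`` lines) carrying the full
simulation configuration, so any file is self-describing and the
round-trip is lossless to full float precision (floats are serialized with
``repr``-faithful precision).
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .config import Boundary, SwarmConfig
from .engine import Trajectory

__all__ = ["write_trajectory", "read_trajectory", "write_manifest"]

_META_KEYS = ("model", "N", "R", "V", "epsilon", "boundary", "L", "m", "seed")


def write_trajectory(traj: Trajectory, path) -> None:
    cfg = traj.config
    meta = {
        "model": cfg.model,
        "N": cfg.N,
        "R": repr(cfg.R),
        "V": repr(cfg.V),
        "epsilon": repr(cfg.epsilon),
        "boundary": cfg.boundary.kind,
        "L": "" if cfg.boundary.L is None else repr(cfg.boundary.L),
        "m": cfg.m,
        "seed": cfg.seed,
        "steps": cfg.steps,
        "init": cfg.init,
        "init_side": repr(cfg.init_side),
    }
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in meta.items():
            fh.write(f"# {k}: {v}\n")
        T, N = traj.T, traj.N
        df = pd.DataFrame(
            {
                "t": np.repeat(np.arange(1, T + 1), N),
                "agent": np.tile(np.arange(N), T),
                "x": traj.xs.ravel(),
                "y": traj.ys.ravel(),
                "d": traj.d.ravel(),
                "h": traj.h.ravel(),
            }
        )
        df.to_csv(fh, index=False, float_format="%.17g")


class TrajectoryParseError(ValueError):
    pass


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    meta: dict[str, str] = {}
    header_line = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if line.startswith("#"):
                body = line[1:].strip()
                if ":" not in body:
                    raise TrajectoryParseError(f"{path}:{lineno}: malformed metadata line")
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            else:
                header_line = lineno
                if line != "t,agent,x,y,d,h":
                    raise TrajectoryParseError(f"{path}:{lineno}: expected header 't,agent,x,y,d,h'")
                break
    missing = [k for k in _META_KEYS if k not in meta]
    if missing:
        raise TrajectoryParseError(f"{path}: metadata block missing keys {missing}")

    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    boundary = Boundary(
        kind=meta["boundary"], L=float(meta["L"]) if meta.get("L") else None
    )
    T = int(df["t"].max())
    cfg = SwarmConfig(
        model=meta["model"],
        N=int(meta["N"]),
        R=float(meta["R"]),
        V=float(meta["V"]),
        epsilon=float(meta["epsilon"]),
        boundary=boundary,
        steps=int(meta.get("steps", T)),
        m=int(meta["m"]),
        seed=int(meta["seed"]),
        init=meta.get("init", "central_area" if boundary.kind == "open" else "uniform_box"),
        init_side=float(meta.get("init_side", 50.0)),
    )
    N = cfg.N
    if len(df) != T * N:
        raise TrajectoryParseError(f"{path}: expected {T * N} data rows, found {len(df)}")
    df = df.sort_values(["t", "agent"], kind="stable")
    shape = (T, N)
    return Trajectory(
        xs=df["x"].to_numpy(float).reshape(shape),
        ys=df["y"].to_numpy(float).reshape(shape),
        d=df["d"].to_numpy(np.int8).reshape(shape),
        h=df["h"].to_numpy(np.int8).reshape(shape),
        config=cfg,
    )


def write_manifest(path, command: str, params: dict, outputs: list[str], t0: float) -> None:
    """Record what produced which files, with wall time."""
    from . import __version__

    manifest = {
        "command": command,
        "params": params,
        "outputs": outputs,
        "version": __version__,
        "wall_time_s": round(time.time() - t0, 3),
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
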