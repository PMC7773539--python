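"""Configuration objects for swarm simulations.

A :class:`SwarmConfig` fully determines a run: the model variant, the
kinematic parameters of the self-propelled particles (neighborhood radius
``R``, speed ``V``, heading-noise amplitude ``epsilon``), the boundary
condition, the initial placement, and the seed.  ``(config, seed)`` is a
pure function to a trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Optional
import math


MODELS = ("SPP", "BO", "BIB")

#: default side of the periodic box (the box side is a free parameter of the
#: wrapped-boundary scenario; 500 length units holds ~1000 agents at a
#: density where a radius-20 neighborhood spans a few percent of the box).
DEFAULT_BOX_SIDE = 500.0


@dataclass(frozen=True)
class Boundary:
    """Boundary condition: ``periodic`` with box side ``L``, or ``open``."""

    kind: str = "open"
    L: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("periodic", "open"):
            raise ValueError(f"boundary kind must be 'periodic' or 'open', got {self.kind!r}")
        if self.kind == "periodic":
            if self.L is None:
                object.__setattr__(self, "L", DEFAULT_BOX_SIDE)
            if not (self.L > 0 and math.isfinite(self.L)):
                raise ValueError("periodic boundary requires finite L > 0")
        elif self.L is not None:
            raise ValueError("open boundary takes no box side")

    @property
    def periodic(self) -> bool:
        return self.kind == "periodic"


@dataclass(frozen=True)
class SwarmConfig:
    """Parameters of one swarm simulation.

    Parameters
    ----------
    model : {"SPP", "BO", "BIB"}
        Plain self-propelled particles (``d`` pinned to 0), particles with
        Bayesian inference only, or with Bayesian plus inverse-Bayesian
        inference.
    N : int
        Number of agents.
    R : float
        Neighborhood radius (length units).
    V : float
        Speed: displacement magnitude per time step.
    epsilon : float
        Maximum magnitude of the per-step heading perturbation (radian);
        the perturbation is ``s * u`` with ``u ~ U[0, epsilon]`` and a fair
        sign ``s``.
    boundary : Boundary
        Periodic (minimum-image distances) or open plane.
    steps : int
        Number of recorded time steps ``T``; the trajectory holds positions
        at ``t = 1 .. T``.
    m : int
        Window size of the inverse-Bayesian data buffer (BIB only).
    seed : int
        Seed of the single per-run random generator.
    init : {"uniform_box", "central_area"}
        Initial placement: uniform over the periodic box, or uniform over a
        central square of side ``init_side``.
    init_side : float
        Side of the central square for ``central_area`` placement.
    """

    model: str = "BIB"
    N: int = 1000
    R: float = 20.0
    V: float = 5.0
    epsilon: float = 0.1
    boundary: Boundary = field(default_factory=Boundary)
    steps: int = 10000
    m: int = 10
    seed: int = 0
    init: str = "uniform_box"
    init_side: float = 50.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.N < 1:
            raise ValueError("N >= 1 required")
        if not self.R > 0:
            raise ValueError("R > 0 required")
        if not self.V > 0:
            raise ValueError("V > 0 required")
        if self.epsilon < 0:
            raise ValueError("epsilon >= 0 required")
        if self.m < 1:
            raise ValueError("m >= 1 required")
        if self.steps < 1:
            raise ValueError("steps >= 1 required")
        if self.init not in ("uniform_box", "central_area"):
            raise ValueError(f"unknown init {self.init!r}")
        if self.init == "central_area" and not self.init_side > 0:
            raise ValueError("central_area requires init_side > 0")
        if self.boundary.periodic and not self.boundary.L > 2 * self.R:
            raise ValueError("periodic boundary requires L > 2R")
        if self.init == "uniform_box" and not self.boundary.periodic:
            raise ValueError("uniform_box init requires a periodic boundary")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["boundary"] = {"kind": self.boundary.kind, "L": self.boundary.L}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SwarmConfig":
        d = dict(d)
        b = d.pop("boundary", {"kind": "open", "L": None})
        if isinstance(b, dict):
            b = Boundary(kind=b.get("kind", "open"), L=b.get("L"))
        return cls(boundary=b, **d)
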