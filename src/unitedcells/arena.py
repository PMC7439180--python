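"""Rectangular arena geometry and constant-speed exploration trajectories.

The simulated agent forages in a closed rectangular box ``[0, width] x
[0, height]`` (meters) at constant speed.  The walk is a correlated random
walk: the heading diffuses with turning noise ``turn_sigma`` (rad per
square-root second, so the per-step heading increment is N(0,
turn_sigma^2 * dt)), the step length is fixed at ``speed * dt``, and the
path reflects specularly off the walls.  The heading persistence time
1/turn_sigma^2 (25 s at the default 0.2) exceeds the Hebbian delays used
downstream, which keeps the lag-tau displacement close to speed*tau.
Its stationary occupancy is close to uniform, which is the regime all later
stages (place-cell recruitment, Hebbian learning, GA sampling) assume.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["Arena", "Trajectory", "random_walk", "frame_walk",
           "min_boundary_distance"]


@dataclass(frozen=True)
class Arena:
    """Closed rectangular exploration space.

    Parameters
    ----------
    width, height
        Side lengths L1, L2 in meters.
    d_max
        Maximum boundary distance at which place cells may be recruited (m).
    field_const
        Distribution constant controlling how fast place-field width grows
        with boundary distance; must exceed 1 so the width interpolation is
        well defined.
    """

    width: float
    height: float
    d_max: float = 20.0
    field_const: float = 30.0

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("arena sides must be positive")
        if self.d_max <= 0:
            raise ValueError("d_max must be positive")
        if self.field_const <= 1:
            raise ValueError("field_const must exceed 1")

    def contains(self, pos: np.ndarray) -> np.ndarray:
        """Element-wise test that positions lie in the closed box."""
        pos = np.asarray(pos, dtype=float)
        x, y = pos[..., 0], pos[..., 1]
        return (x >= 0) & (x <= self.width) & (y >= 0) & (y <= self.height)


def min_boundary_distance(arena: Arena, pos: np.ndarray) -> np.ndarray:
    """Minimum Euclidean distance from ``pos`` to the four walls.

    Works on a single ``(x, y)`` pair or an ``(n, 2)`` array.  Raises
    ``ValueError`` for positions outside the closed arena.
    """
    pos = np.asarray(pos, dtype=float)
    if not np.all(arena.contains(pos)):
        raise ValueError("position outside arena")
    x, y = pos[..., 0], pos[..., 1]
    return np.minimum(
        np.minimum(x, arena.width - x), np.minimum(y, arena.height - y)
    )


@dataclass
class Trajectory:
    """Sequence of positions visited at fixed time step ``dt``."""

    positions: np.ndarray  # (n, 2) meters
    dt: float
    speed: float
    seed: int | None = None
    turn_sigma: float = field(default=0.2)

    @property
    def n_steps(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_steps) * self.dt

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        df = pd.DataFrame(
            {
                "step": np.arange(self.n_steps),
                "t": self.times,
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
            }
        )
        df.to_csv(path, index=False)
        meta = {"dt": self.dt, "v": self.speed, "seed": self.seed,
                "turn_sigma": self.turn_sigma}
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "Trajectory":
        path = Path(path)
        df = pd.read_csv(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            positions=df[["x", "y"]].to_numpy(),
            dt=float(meta["dt"]),
            speed=float(meta["v"]),
            seed=meta.get("seed"),
            turn_sigma=float(meta.get("turn_sigma", 0.2)),
        )


def _fold(u: np.ndarray, length: float) -> np.ndarray:
    # billiard unfolding: specular reflection off 0 and `length` equals
    # folding the free path with a period-2L triangle wave
    return length - np.abs(np.mod(u, 2.0 * length) - length)


def random_walk(
    arena: Arena,
    speed: float,
    duration: float,
    dt: float = 1.0,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    turn_sigma: float = 0.2,
) -> Trajectory:
    """Correlated random walk with specular wall reflection.

    The heading angle evolves by i.i.d. ``N(0, turn_sigma^2 * dt)``
    increments per step (``turn_sigma`` in rad/sqrt(s)); every step moves
    exactly ``speed * dt`` along the (possibly reflected) path, so path
    length is conserved at the walls.  Long runs cover the arena with
    near-uniform occupancy.
    """
    if duration <= 0 or dt <= 0 or speed <= 0:
        raise ValueError("duration, dt and speed must be positive")
    if speed * dt >= min(arena.width, arena.height):
        raise ValueError("step length must be smaller than the arena")
    n = int(round(duration / dt))
    if rng is None:
        rng = np.random.default_rng(seed)
    start = rng.uniform([0.0, 0.0], [arena.width, arena.height])
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    step_sigma = turn_sigma * np.sqrt(dt)
    theta = theta0 + np.concatenate(
        [[0.0], np.cumsum(rng.normal(0.0, step_sigma, n - 1))]
    )
    steps = speed * dt * np.column_stack([np.cos(theta), np.sin(theta)])
    free = start + np.concatenate(
        [np.zeros((1, 2)), np.cumsum(steps[:-1], axis=0)]
    )
    positions = np.column_stack(
        [_fold(free[:, 0], arena.width), _fold(free[:, 1], arena.height)]
    )
    return Trajectory(positions=positions, dt=dt, speed=speed, seed=seed,
                      turn_sigma=turn_sigma)


def frame_walk(
    arena: Arena,
    width: float,
    speed: float,
    duration: float,
    dt: float = 1.0,
    *,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    turn_sigma: float = 0.2,
) -> Trajectory:
    """Correlated walk confined to the frame of ``width`` along the walls.

    The walk runs in an unrolled strip (perimeter coordinate x distance to
    the outer wall) and is wrapped back onto the rectangular ring, so the
    agent circulates through the boundary zone with near-uniform occupancy
    there and never enters the central rectangle.  Used for the weight
    learning stage, whose drive lives entirely within ``width`` (= D) of a
    wall; walking the empty center would only dilute the visit rate.
    Distances are slightly distorted where the strip turns a corner.
    """
    if width <= 0 or width > min(arena.width, arena.height) / 2:
        raise ValueError("width must lie in (0, min(L1, L2)/2]")
    W, H = arena.width, arena.height
    strip = Arena(2 * (W + H), width, d_max=arena.d_max,
                  field_const=arena.field_const)
    walk = random_walk(strip, speed, duration, dt, seed=seed, rng=rng,
                       turn_sigma=turn_sigma)
    u = np.mod(walk.positions[:, 0], 2 * (W + H))
    t = walk.positions[:, 1]  # distance from the outer wall
    pos = np.empty_like(walk.positions)
    m1 = u < W
    m2 = (u >= W) & (u < W + H)
    m3 = (u >= W + H) & (u < 2 * W + H)
    m4 = u >= 2 * W + H
    pos[m1, 0] = u[m1]
    pos[m1, 1] = t[m1]
    pos[m2, 0] = W - t[m2]
    pos[m2, 1] = u[m2] - W
    pos[m3, 0] = W - (u[m3] - (W + H))
    pos[m3, 1] = H - t[m3]
    pos[m4, 0] = t[m4]
    pos[m4, 1] = H - (u[m4] - (2 * W + H))
    return Trajectory(positions=pos, dt=dt, speed=speed, seed=seed,
                      turn_sigma=turn_sigma)
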