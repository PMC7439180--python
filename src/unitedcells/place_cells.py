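"""Boundary-driven visual place cells with distance-dependent field widths.

Each visual place cell fires as an isotropic 2-D Gaussian,

    R_i(x, y) = A * exp(-((x - x_i)^2 + (y - y_i)^2) / sigma_i^2),

whose width parameter sigma_i is set at recruitment time by the minimum
distance d from the recruitment location to the arena boundary:

    sigma(d) = l_min^((L - d)/(L - 1)) * l_max^((d - 1)/(L - 1)),   d <= D.

A new cell is recruited at the current location whenever every existing
cell fires below half its maximum rate A/2 there and the location is within
D meters of a wall.  The result is a dense carpet of narrow fields along
the boundary thinning into wide, sparse fields toward the interior.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import Arena, Trajectory, min_boundary_distance

__all__ = [
    "HALF_MAX_FACTOR",
    "PlaceCell",
    "PlaceMap",
    "sigma_of_distance",
    "place_rate",
    "population_rates",
    "recruit_step",
    "run_recruitment",
]

#: The field drops to half its peak rate at radius sigma * sqrt(ln 2).
HALF_MAX_FACTOR = float(np.sqrt(np.log(2.0)))


@dataclass(frozen=True)
class PlaceCell:
    id: int
    x: float
    y: float
    sigma: float
    max_rate: float

    def __post_init__(self) -> None:
        if self.sigma <= 0 or self.max_rate <= 0:
            raise ValueError("sigma and max_rate must be positive")

    @property
    def half_max_radius(self) -> float:
        return self.sigma * HALF_MAX_FACTOR


def sigma_of_distance(
    d, l_min: float, l_max: float, field_const: float, d_max: float
):
    """Field width as a geometric interpolation between l_min and l_max.

    Raises ``ValueError`` outside ``0 <= d <= d_max`` (no place cell may be
    generated beyond d_max).  At d = 1 the width is exactly l_min; it grows
    monotonically with d when l_max > l_min.  For d < 1 the formula is
    evaluated as written, giving widths slightly below l_min.
    """
    d = np.asarray(d, dtype=float)
    if np.any(d < 0) or np.any(d > d_max):
        raise ValueError("boundary distance outside [0, d_max]")
    L = field_const
    sig = l_min ** ((L - d) / (L - 1.0)) * l_max ** ((d - 1.0) / (L - 1.0))
    return float(sig) if sig.ndim == 0 else sig


def place_rate(cell: PlaceCell, pos) -> float:
    """Gaussian firing rate of one cell at ``pos`` (Hz)."""
    pos = np.asarray(pos, dtype=float)
    dx = pos[..., 0] - cell.x
    dy = pos[..., 1] - cell.y
    r = cell.max_rate * np.exp(-(dx**2 + dy**2) / cell.sigma**2)
    return float(r) if np.ndim(r) == 0 else r


class PlaceMap:
    """Ordered collection of recruited place cells.

    Stores centers/widths in growing numpy buffers so that per-step
    recruitment checks and population-rate queries stay vectorized.
    """

    def __init__(
        self,
        l_min: float = 1.0,
        l_max: float = 15.0,
        field_const: float = 30.0,
        d_max: float = 20.0,
        max_rate: float = 10.0,
    ) -> None:
        if l_min <= 0 or l_max <= 0 or max_rate <= 0:
            raise ValueError("l_min, l_max, max_rate must be positive")
        if field_const <= 1:
            raise ValueError("field_const must exceed 1")
        self.l_min = l_min
        self.l_max = l_max
        self.field_const = field_const
        self.d_max = d_max
        self.max_rate = max_rate
        self._n = 0
        cap = 256
        self._centers = np.empty((cap, 2))
        self._sigmas = np.empty(cap)
        self._recruit_steps = np.empty(cap, dtype=np.int64)

    # -- container protocol -------------------------------------------------
    def __len__(self) -> int:
        return self._n

    def __getitem__(self, i: int) -> PlaceCell:
        if not -self._n <= i < self._n:
            raise IndexError(i)
        i %= self._n
        return PlaceCell(
            id=i,
            x=float(self._centers[i, 0]),
            y=float(self._centers[i, 1]),
            sigma=float(self._sigmas[i]),
            max_rate=self.max_rate,
        )

    @property
    def centers(self) -> np.ndarray:
        return self._centers[: self._n]

    @property
    def sigmas(self) -> np.ndarray:
        return self._sigmas[: self._n]

    @property
    def recruit_steps(self) -> np.ndarray:
        return self._recruit_steps[: self._n]

    @property
    def half_max_radii(self) -> np.ndarray:
        return self.sigmas * HALF_MAX_FACTOR

    def append(self, x: float, y: float, sigma: float, step: int = -1) -> None:
        if self._n == len(self._sigmas):
            grow = len(self._sigmas) * 2
            self._centers = np.resize(self._centers, (grow, 2))
            self._sigmas = np.resize(self._sigmas, grow)
            self._recruit_steps = np.resize(self._recruit_steps, grow)
        self._centers[self._n] = (x, y)
        self._sigmas[self._n] = sigma
        self._recruit_steps[self._n] = step
        self._n += 1

    # -- rates --------------------------------------------------------------
    def rates(self, pos) -> np.ndarray:
        """Population rate vector (Hz per cell) at a single position."""
        pos = np.asarray(pos, dtype=float)
        d2 = np.sum((self.centers - pos) ** 2, axis=1)
        return self.max_rate * np.exp(-d2 / self.sigmas**2)

    def rates_at(self, positions: np.ndarray, chunk: int = 2048) -> np.ndarray:
        """Rate matrix (n_positions, n_cells), computed in chunks."""
        positions = np.asarray(positions, dtype=float)
        out = np.empty((len(positions), self._n))
        inv = 1.0 / self.sigmas**2
        for a in range(0, len(positions), chunk):
            b = min(a + chunk, len(positions))
            d2 = (
                (positions[a:b, None, 0] - self.centers[None, :, 0]) ** 2
                + (positions[a:b, None, 1] - self.centers[None, :, 1]) ** 2
            )
            out[a:b] = self.max_rate * np.exp(-d2 * inv[None, :])
        return out

    def covered(self, pos) -> bool:
        """True iff some existing cell fires >= A/2 at ``pos``.

        Equivalent to ``max(rates(pos)) >= A/2`` but avoids exponentials:
        the field exceeds half-max exactly inside radius sigma*sqrt(ln 2).
        """
        pos = np.asarray(pos, dtype=float)
        d2 = np.sum((self.centers - pos) ** 2, axis=1)
        r2 = np.log(2.0) * self.sigmas**2
        return bool(np.any(d2 <= r2))

    # -- persistence --------------------------------------------------------
    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        pd.DataFrame(
            {
                "id": np.arange(self._n),
                "x": self.centers[:, 0],
                "y": self.centers[:, 1],
                "sigma": self.sigmas,
                "recruit_step": self.recruit_steps,
            }
        ).to_csv(path, index=False)
        meta = {
            "l_min": self.l_min,
            "l_max": self.l_max,
            "field_const": self.field_const,
            "d_max": self.d_max,
            "max_rate": self.max_rate,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "PlaceMap":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        pmap = cls(**meta)
        df = pd.read_csv(path)
        for row in df.itertuples(index=False):
            pmap.append(row.x, row.y, row.sigma, int(row.recruit_step))
        return pmap


def population_rates(pmap: PlaceMap, pos) -> np.ndarray:
    """Vectorized Gaussian rates of every cell at one position."""
    return pmap.rates(pos)


def recruit_step(pmap: PlaceMap, pos, arena: Arena, step: int = -1) -> bool:
    """Apply the recruitment rule at one location; True if a cell was added."""
    d = float(min_boundary_distance(arena, pos))
    if d > pmap.d_max:
        return False
    if pmap.covered(pos):
        return False
    sigma = sigma_of_distance(
        d, pmap.l_min, pmap.l_max, pmap.field_const, pmap.d_max
    )
    pmap.append(float(pos[0]), float(pos[1]), sigma, step)
    return True


def run_recruitment(
    trajectory: Trajectory,
    arena: Arena,
    *,
    l_min: float = 1.0,
    l_max: float = 15.0,
    max_rate: float = 10.0,
    check_interval: float = 1.0,
) -> PlaceMap:
    """Run the recruitment rule along a trajectory and return the map.

    The rule is evaluated every ``check_interval`` seconds (default once
    per second) even when the trajectory is sampled more finely for the
    downstream weight dynamics.  Deterministic given the trajectory; the
    recruitment step index of every cell is recorded.
    """
    pmap = PlaceMap(
        l_min=l_min,
        l_max=l_max,
        field_const=arena.field_const,
        d_max=arena.d_max,
        max_rate=max_rate,
    )
    stride = max(1, int(round(check_interval / trajectory.dt)))
    pos = trajectory.positions[::stride]
    x, y = pos[:, 0], pos[:, 1]
    d_all = np.minimum(
        np.minimum(x, arena.width - x), np.minimum(y, arena.height - y)
    )
    eligible = d_all <= pmap.d_max
    ln2 = np.log(2.0)
    for t in np.flatnonzero(eligible):
        p = pos[t]
        d2 = np.sum((pmap.centers - p) ** 2, axis=1)
        if np.any(d2 <= ln2 * pmap.sigmas**2):
            continue
        sigma = sigma_of_distance(
            d_all[t], pmap.l_min, pmap.l_max, pmap.field_const, pmap.d_max
        )
        pmap.append(float(p[0]), float(p[1]), sigma, int(t * stride))
    return pmap
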