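"""Oscillatory-interference grid-cell rate model and hexagonality diagnostics.

A grid cell's firing over the plane is the interference pattern of three
cosine gratings whose wave vectors are 60 degrees apart:

    G(r) = C * (2/3) * [ (1/3) * sum_{d=1..3} cos(f * k_d . (r - phi)) + 1/2 ],
    k_d = (cos(omega + (2d-1) pi/3), sin(omega + (2d-1) pi/3)),
    f   = 4 pi / (sqrt(3) B).

With this angular frequency the rate lies in [0, C], peaks at exactly C on
a triangular lattice with nearest-neighbor spacing B, and phi/omega shift
and rotate the lattice.  C is the maximum rate (Hz), B the field spacing
(m), phi = (x0, y0) the field phase and omega the field direction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, signal

from .arena import Arena

__all__ = ["GridParams", "RateMap", "grid_rate", "rate_map", "gridness_score"]


@dataclass(frozen=True)
class GridParams:
    max_rate: float  # C, Hz
    spacing: float  # B, m
    phase_x: float  # x0, m
    phase_y: float  # y0, m
    orientation: float  # omega, rad

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.max_rate, self.spacing, self.phase_x, self.phase_y,
             self.orientation]
        )


def grid_rate(params: GridParams, pos) -> np.ndarray:
    """Three-cosine interference rate at one position or an (n, 2) array."""
    if params.spacing <= 0:
        raise ValueError("spacing B must be positive")
    pos = np.asarray(pos, dtype=float)
    rel_x = pos[..., 0] - params.phase_x
    rel_y = pos[..., 1] - params.phase_y
    f = 4.0 * np.pi / (np.sqrt(3.0) * params.spacing)
    angles = params.orientation + (2.0 * np.arange(1, 4) - 1.0) * np.pi / 3.0
    acc = 0.0
    for a in angles:
        acc = acc + np.cos(f * (np.cos(a) * rel_x + np.sin(a) * rel_y))
    r = params.max_rate * (2.0 / 3.0) * (acc / 3.0 + 0.5)
    return float(r) if np.ndim(r) == 0 else r


def grid_rate_many(param_array: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Rates for many parameter sets at many positions.

    ``param_array`` is (n_cand, 5) in the order (C, B, x0, y0, omega);
    returns (n_cand, n_pos).  Used by the GA fitness evaluation.
    """
    p = np.asarray(param_array, dtype=float)
    positions = np.asarray(positions, dtype=float)
    C, B, x0, y0, om = (p[:, i] for i in range(5))
    if np.any(B <= 0):
        raise ValueError("spacing B must be positive")
    f = 4.0 * np.pi / (np.sqrt(3.0) * B)  # (n_cand,)
    rel_x = positions[None, :, 0] - x0[:, None]
    rel_y = positions[None, :, 1] - y0[:, None]
    acc = np.zeros_like(rel_x)
    for d in (1.0, 2.0, 3.0):
        a = om + (2.0 * d - 1.0) * np.pi / 3.0
        acc += np.cos(
            f[:, None] * (np.cos(a)[:, None] * rel_x + np.sin(a)[:, None] * rel_y)
        )
    return C[:, None] * (2.0 / 3.0) * (acc / 3.0 + 0.5)


@dataclass
class RateMap:
    """Cell-centered raster of firing rates over the arena."""

    values: np.ndarray  # (ny, nx)
    resolution: float

    @property
    def x(self) -> np.ndarray:
        return (np.arange(self.values.shape[1]) + 0.5) * self.resolution

    @property
    def y(self) -> np.ndarray:
        return (np.arange(self.values.shape[0]) + 0.5) * self.resolution


def rate_map(params: GridParams, arena: Arena, resolution: float) -> RateMap:
    """Evaluate the grid rate on a cell-centered lattice covering the arena."""
    if resolution <= 0:
        raise ValueError("resolution must be positive")
    nx = max(1, int(round(arena.width / resolution)))
    ny = max(1, int(round(arena.height / resolution)))
    xs = (np.arange(nx) + 0.5) * resolution
    ys = (np.arange(ny) + 0.5) * resolution
    gx, gy = np.meshgrid(xs, ys)
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    vals = grid_rate(params, pts).reshape(ny, nx)
    return RateMap(values=vals, resolution=resolution)


def _autocorrelogram(z: np.ndarray) -> np.ndarray:
    """Pearson-normalized 2-D spatial autocorrelogram (full extent)."""
    z = z - z.mean()
    num = signal.fftconvolve(z, z[::-1, ::-1], mode="full")
    ones = np.ones_like(z)
    n_overlap = signal.fftconvolve(ones, ones, mode="full")
    denom = z.std() ** 2 * n_overlap
    with np.errstate(invalid="ignore", divide="ignore"):
        ac = num / denom
    return np.nan_to_num(ac)


def gridness_score(rmap: RateMap) -> float:
    """Rotational-symmetry gridness of a rate map.

    Computes the spatial autocorrelogram, masks an annulus around the
    central peak, and correlates the annulus with itself rotated by 30, 60,
    90, 120 and 150 degrees:

        gridness = min(corr60, corr120) - max(corr30, corr90, corr150).

    Positive for hexagonal fields, negative for stripes, 0 by convention
    for structureless (constant) maps.  The map must span at least a few
    field periods for the annulus to exist.
    """
    z = np.asarray(rmap.values, dtype=float)
    if min(z.shape) < 8:
        raise ValueError("rate map too small for a gridness estimate")
    if z.std() == 0:
        return 0.0
    ac = _autocorrelogram(z)
    cy, cx = (np.array(ac.shape) - 1) // 2
    yy, xx = np.indices(ac.shape)
    rr = np.hypot(yy - cy, xx - cx)
    # radial mean to find the central peak's first zero crossing
    r_int = rr.astype(int)
    radial = np.bincount(r_int.ravel(), weights=ac.ravel()) / np.bincount(
        r_int.ravel()
    )
    neg = np.flatnonzero(radial < 0)
    if len(neg) == 0:
        raise ValueError("no zero crossing: map spans too few periods")
    r_in = float(neg[0])
    r_out = min(2.5 * r_in, min(cy, cx))
    if r_out <= r_in + 2:
        raise ValueError("annulus degenerate: map spans too few periods")
    mask = (rr >= r_in) & (rr <= r_out)
    base = ac[mask]
    corrs = {}
    for deg in (30, 60, 90, 120, 150):
        rot = ndimage.rotate(ac, deg, reshape=False, order=1, mode="constant")
        r = rot[mask]
        corrs[deg] = float(np.corrcoef(base, r)[0, 1])
    return min(corrs[60], corrs[120]) - max(corrs[30], corrs[90], corrs[150])
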