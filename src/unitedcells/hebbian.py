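"""Delayed-Hebbian feedforward learning of place-to-grid weights.

A single downstream grid cell receives the whole place-cell population
through a weight vector E.  Weights evolve along the trajectory by the
delayed Hebbian rule

    eta^-1 dE_n/dt = -E_n + [R_n(t) - h R_n(t - tau)] G(t) + S,

where G(t) = sum_i E_i R_i(t) is the grid cell's instantaneous rate, tau
is the weight-update time interval (seconds), h scales the delayed
presynaptic rate, and S is a constant drive.  The rule is iterated once
per trajectory sample (0.1 s steps by default, eta per update) with a
tau-deep ring buffer holding the delayed rates.  After every step a competitive
restriction is applied: weights below Th_down are clipped up to Th_down,
and if any weight exceeds Th_up the whole vector is rescaled so the maximum
equals Th_up.  The delayed, sign-flipped term gives the input correlation
an effective center-surround (Mexican-hat) profile along the walk, which is
what drives the weights into spatially periodic bands whose period grows
with tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Arena, Trajectory
from .place_cells import PlaceMap

__all__ = [
    "HebbianParams",
    "GridWeights",
    "VisualGridCell",
    "grid_rate",
    "hebbian_step",
    "apply_weight_bounds",
    "train_weights",
    "split_by_boundary",
    "visual_grid_rate",
    "set_normalization",
    "boundary_profile",
    "dominant_period",
]

BOUNDARIES = ("x=0", "x=L1", "y=0", "y=L2")


@dataclass(frozen=True)
class HebbianParams:
    eta: float = 5e-6
    h: float = 5.0
    s_const: float = 7.0
    th_down: float = 0.0
    th_up: float = 5.0

    def __post_init__(self) -> None:
        if not self.th_down < self.th_up:
            raise ValueError("th_down must be below th_up")


@dataclass
class GridWeights:
    """Learned weight vector plus the hyper-parameters that produced it."""

    E: np.ndarray
    tau: float  # delay in seconds
    params: HebbianParams = field(default_factory=HebbianParams)

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")


def grid_rate(E: np.ndarray, rates: np.ndarray) -> float:
    """Grid-cell rate G = E . R (Hz)."""
    E = np.asarray(E, dtype=float)
    rates = np.asarray(rates, dtype=float)
    if E.shape != rates.shape:
        raise ValueError("weight and rate vectors differ in length")
    return float(E @ rates)


def apply_weight_bounds(E: np.ndarray, th_down: float, th_up: float) -> np.ndarray:
    """Lower clip, then subtractive competitive normalization.

    Whenever any weight exceeds the upper bound, the *same* amount
    (max(E) - th_up) is subtracted from every weight and the result is
    lower-clipped again, so the maximum lands exactly on th_up.  Taking the
    same amount from every weight (rather than the same factor) makes the
    competition winner-take-all: weights are driven toward the two bounds,
    which is what produces high-contrast periodic weight patterns.
    """
    if not th_down < th_up:
        raise ValueError("th_down must be below th_up")
    E = np.maximum(np.asarray(E, dtype=float), th_down)
    m = E.max(initial=-np.inf)
    if m > th_up:
        E = np.maximum(E - (m - th_up), th_down)
    return E


def hebbian_step(
    E: np.ndarray,
    rates_now: np.ndarray,
    rates_delayed: np.ndarray,
    params: HebbianParams,
    dt: float = 1.0,
) -> np.ndarray:
    """One forward-Euler update followed by the competitive bounds."""
    E = np.asarray(E, dtype=float)
    rates_now = np.asarray(rates_now, dtype=float)
    rates_delayed = np.asarray(rates_delayed, dtype=float)
    if rates_now.shape != E.shape or rates_delayed.shape != E.shape:
        raise ValueError("rate vectors must match weight length")
    G = E @ rates_now
    dE = params.eta * (-E + (rates_now - params.h * rates_delayed) * G
                       + params.s_const)
    return apply_weight_bounds(E + dt * dE, params.th_down, params.th_up)


def train_weights(
    trajectory: Trajectory,
    pmap: PlaceMap,
    tau: float,
    params: HebbianParams = HebbianParams(),
    *,
    rng: np.random.Generator | None = None,
    init: np.ndarray | None = None,
    use_numba: bool = True,
) -> GridWeights:
    """Train one weight vector along a trajectory.

    ``tau`` is the delay in seconds; the delay buffer holds
    ``round(tau / trajectory.dt)`` past rate vectors and updates start once
    it is full.  The learning rate ``eta`` is applied per update at the
    trajectory's sampling step (the dynamics are simulated at that step,
    typically 0.1 s).  Initial weights are i.i.d. uniform over the full
    admissible range [th_down, th_up] unless ``init`` is given, so the
    competitive restriction is active from the start.
    """
    if tau <= 0:
        raise ValueError("tau must be positive")
    tau_steps = int(round(tau / trajectory.dt))
    if tau_steps < 1:
        raise ValueError("tau must be at least one trajectory step")
    n_steps = trajectory.n_steps
    if n_steps <= tau_steps:
        raise ValueError("trajectory shorter than the delay tau")
    n = len(pmap)
    if init is not None:
        E = np.array(init, dtype=float)
        if E.shape != (n,):
            raise ValueError("init has wrong length")
    else:
        if rng is None:
            rng = np.random.default_rng()
        E = rng.uniform(params.th_down, params.th_up, n)
    E = apply_weight_bounds(E, params.th_down, params.th_up)
    eta, h, S = params.eta, params.h, params.s_const
    lo, up = params.th_down, params.th_up

    if use_numba:
        from ._kernels import HAVE_NUMBA, hebbian_train_loop

        if HAVE_NUMBA:
            E = hebbian_train_loop(
                np.ascontiguousarray(trajectory.positions, dtype=float),
                np.ascontiguousarray(pmap.centers, dtype=float),
                1.0 / pmap.sigmas**2,
                float(pmap.max_rate),
                E,
                tau_steps,
                eta, h, S, lo, up,
            )
            return GridWeights(E=E, tau=tau, params=params)

    ring = np.empty((tau_steps, n))
    for t in range(n_steps):
        r_now = pmap.rates(trajectory.positions[t])
        if t >= tau_steps:
            r_del = ring[t % tau_steps]
            G = float(E @ r_now)
            E += eta * (-E + (r_now - h * r_del) * G + S)
            np.maximum(E, lo, out=E)
            m = E.max()
            if m > up:
                np.maximum(E - (m - up), lo, out=E)
        ring[t % tau_steps] = r_now
    return GridWeights(E=E, tau=tau, params=params)


# ---------------------------------------------------------------------------
# boundary-wise visual grid cells


@dataclass
class VisualGridCell:
    """Sub-population of place cells nearest one wall, with their weights.

    The raw rate is sum_n E_n R_n over member cells; ``norm`` rescales it so
    the maximum over the sampling-region grid is 1 Hz (set separately once
    the sampling region is known).
    """

    boundary: str
    member_ids: np.ndarray
    weights: np.ndarray
    tau: float
    norm: float | None = None


def split_by_boundary(
    pmap: PlaceMap, gw: GridWeights, arena: Arena
) -> list[VisualGridCell]:
    """Partition place cells by nearest wall, tie order x=0, x=L1, y=0, y=L2."""
    c = pmap.centers
    dists = np.stack(
        [c[:, 0], arena.width - c[:, 0], c[:, 1], arena.height - c[:, 1]]
    )
    nearest = np.argmin(dists, axis=0)  # first minimum wins ties
    out = []
    for b, name in enumerate(BOUNDARIES):
        ids = np.flatnonzero(nearest == b)
        out.append(
            VisualGridCell(
                boundary=name,
                member_ids=ids,
                weights=gw.E[ids].copy(),
                tau=gw.tau,
            )
        )
    return out


def _raw_rate(vgc: VisualGridCell, pmap: PlaceMap, positions: np.ndarray,
              chunk: int = 4096) -> np.ndarray:
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    centers = pmap.centers[vgc.member_ids]
    inv = 1.0 / pmap.sigmas[vgc.member_ids] ** 2
    out = np.empty(len(positions))
    for a in range(0, len(positions), chunk):
        b = min(a + chunk, len(positions))
        d2 = (
            (positions[a:b, None, 0] - centers[None, :, 0]) ** 2
            + (positions[a:b, None, 1] - centers[None, :, 1]) ** 2
        )
        out[a:b] = (pmap.max_rate * np.exp(-d2 * inv[None, :])) @ vgc.weights
    return out


def set_normalization(
    vgc: VisualGridCell, pmap: PlaceMap, region_points: np.ndarray
) -> None:
    """Fix the scale so the max rate over the sampling-region grid is 1 Hz."""
    raw = _raw_rate(vgc, pmap, region_points)
    m = raw.max(initial=0.0)
    if m <= 0:
        raise ValueError("visual grid cell silent over the sampling region")
    vgc.norm = 1.0 / m


def visual_grid_rate(
    vgc: VisualGridCell, pmap: PlaceMap, positions: np.ndarray
) -> np.ndarray:
    """Normalized visual-grid-cell rate at positions (Hz, max 1 in region)."""
    if vgc.norm is None:
        raise ValueError("normalization not computed; call set_normalization")
    return vgc.norm * _raw_rate(vgc, pmap, positions)


# ---------------------------------------------------------------------------
# periodicity diagnostics along a boundary band


def boundary_profile(
    pmap: PlaceMap,
    gw: GridWeights,
    arena: Arena,
    boundary: str,
    band: float = 5.0,
    bin_width: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Mean weight vs. along-wall coordinate for cells within ``band`` of a wall.

    Returns (bin centers, mean weight per bin); empty bins carry the profile
    mean so spectra are not distorted by gaps.
    """
    c = pmap.centers
    if boundary == "x=0":
        sel, coord, extent = c[:, 0] <= band, c[:, 1], arena.height
    elif boundary == "x=L1":
        sel, coord, extent = arena.width - c[:, 0] <= band, c[:, 1], arena.height
    elif boundary == "y=0":
        sel, coord, extent = c[:, 1] <= band, c[:, 0], arena.width
    elif boundary == "y=L2":
        sel, coord, extent = arena.height - c[:, 1] <= band, c[:, 0], arena.width
    else:
        raise ValueError(f"unknown boundary {boundary!r}")
    edges = np.arange(0.0, extent + bin_width, bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    idx = np.clip(np.digitize(coord[sel], edges) - 1, 0, len(centers) - 1)
    sums = np.bincount(idx, weights=gw.E[sel], minlength=len(centers))
    counts = np.bincount(idx, minlength=len(centers))
    prof = np.full(len(centers), np.nan)
    nz = counts > 0
    prof[nz] = sums[nz] / counts[nz]
    prof[~nz] = prof[nz].mean()
    return centers, prof


def dominant_period(
    profile: np.ndarray,
    bin_width: float = 1.0,
    min_period: float | None = None,
    max_period: float | None = None,
) -> tuple[float, float]:
    """(period of the strongest frequency, its power / median power).

    The profile is mean-subtracted and Fourier transformed; the returned
    ratio compares the dominant peak with the median power of the whole
    nonzero-frequency spectrum and is the periodicity statistic used to
    decide whether banding emerged.  ``min_period``/``max_period`` restrict
    the *search* to a physical band-period window (the profile envelope
    otherwise dominates with a wall-length period); the median stays global
    so the ratio remains comparable across windows.
    """
    z = np.asarray(profile, dtype=float)
    z = z - z.mean()
    power = np.abs(np.fft.rfft(z)) ** 2
    freqs = np.fft.rfftfreq(len(z), d=bin_width)
    power, freqs = power[1:], freqs[1:]  # drop DC
    med = float(np.median(power))
    sel = np.ones(len(freqs), dtype=bool)
    if max_period is not None:
        sel &= freqs >= 1.0 / max_period
    if min_period is not None:
        sel &= freqs <= 1.0 / min_period
    if not np.any(sel):
        raise ValueError("period window excludes every frequency bin")
    k = np.flatnonzero(sel)[int(np.argmax(power[sel]))]
    ratio = float(power[k] / med) if med > 0 else np.inf
    return float(1.0 / freqs[k]), ratio
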