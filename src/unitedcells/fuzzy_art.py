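"""Fuzzy ART clustering and its supervised use to generate united place cells.

Fuzzy adaptive resonance theory (ART) clusters inputs incrementally.  An
input I in [0,1]^p is complement coded, H = [I, 1 - I], which conserves its
1-norm at p.  Each committed category j holds a weight vector w_j
(initialized at all ones).  Presentation of H proceeds by:

  choice      T_j = |H ^ w_j| / (alpha + |w_j|)      (^ = componentwise min)
  match       |H ^ w_J| >= rho * |H|                 (vigilance test)
  learning    w_J <- beta (H ^ w_J) + (1 - beta) w_J (fast when beta = 1)

Categories are tried in decreasing T_j (smallest index on ties); if none
passes the vigilance test a fresh all-ones node is committed.

The supervised simplification used here replaces ARTMAP's second ART
module with spatial *types*: each visual place cell's half-max field is one
type and the remaining space is a background type.  For every type inside
the GA sampling region, the vigilance rho is lowered from 1 in steps of
0.001 until the type's locations (sampled on a 0.5 m lattice of grid-cell
population rates) collapse into exactly one category; the mean learned rho
then clusters all remaining types.  Every resulting category is a united
place cell, centered at the centroid of its member locations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .arena import Arena
from .grid_model import GridParams, grid_rate
from .place_cells import PlaceMap

__all__ = [
    "FuzzyArt",
    "complement_code",
    "choice",
    "vigilance_match",
    "learn",
    "assign_type",
    "grid_population_input",
    "learn_vigilance",
    "UnitedPlaceCell",
    "generate_united_place_cells",
    "BACKGROUND",
]

#: Type label for locations where no place cell fires above half-max.
BACKGROUND = -1


def complement_code(I: np.ndarray) -> np.ndarray:
    """H = [I, 1 - I]; conserves the 1-norm at p.  Accepts (p,) or (n, p)."""
    I = np.asarray(I, dtype=float)
    if np.any(I < 0) or np.any(I > 1):
        raise ValueError("inputs must lie in [0, 1]")
    return np.concatenate([I, 1.0 - I], axis=-1)


def choice(H: np.ndarray, w: np.ndarray, alpha: float) -> float:
    """Selection function T_j = |H ^ w_j| / (alpha + |w_j|)."""
    H = np.asarray(H, dtype=float)
    w = np.asarray(w, dtype=float)
    if H.shape != w.shape:
        raise ValueError("length mismatch")
    return float(np.minimum(H, w).sum() / (alpha + w.sum()))


def vigilance_match(
    H: np.ndarray, w: np.ndarray, rho: float
) -> tuple[bool, np.ndarray]:
    """Match test: X = H ^ w_J passes iff |X| >= rho |H|."""
    H = np.asarray(H, dtype=float)
    w = np.asarray(w, dtype=float)
    if H.shape != w.shape:
        raise ValueError("length mismatch")
    X = np.minimum(H, w)
    return bool(X.sum() >= rho * H.sum()), X


def learn(w: np.ndarray, H: np.ndarray, beta: float) -> np.ndarray:
    """Convex weight update toward H ^ w; componentwise non-increasing."""
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    w = np.asarray(w, dtype=float)
    H = np.asarray(H, dtype=float)
    return beta * np.minimum(H, w) + (1.0 - beta) * w


class FuzzyArt:
    """Incremental fuzzy ART network over complement-coded inputs."""

    def __init__(self, dim: int, alpha: float = 0.001, beta: float = 1.0,
                 rho: float = 0.5) -> None:
        if not 0.0 <= rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")
        if alpha < 0:
            raise ValueError("alpha must be nonnegative")
        self.dim = dim  # p (inputs are 2p after complement coding)
        self.alpha = alpha
        self.beta = beta
        self.rho = rho
        self._w = np.empty((0, 2 * dim))

    @property
    def n_categories(self) -> int:
        return len(self._w)

    @property
    def weights(self) -> np.ndarray:
        return self._w

    def present(self, H: np.ndarray) -> int:
        """Present one complement-coded input; returns the winning category.

        Equivalent to the sequential select-test-reset loop: both the choice
        value and the match ratio are fixed during one presentation, so the
        winner is the highest-T category that passes vigilance (smallest
        index on ties); if none passes, a fresh all-ones node is committed
        and learned into.
        """
        H = np.asarray(H, dtype=float)
        if H.shape != (2 * self.dim,):
            raise ValueError("input must be complement coded (length 2p)")
        norm_H = H.sum()
        if self.n_categories:
            overlap = np.minimum(self._w, H[None, :]).sum(axis=1)
            T = overlap / (self.alpha + self._w.sum(axis=1))
            passes = overlap >= self.rho * norm_H
            if np.any(passes):
                # stable argsort on -T => decreasing T, smallest index first
                order = np.argsort(-T, kind="stable")
                J = int(order[np.argmax(passes[order])])
                if passes[J]:
                    self._w[J] = learn(self._w[J], H, self.beta)
                    return J
        w_new = learn(np.ones(2 * self.dim), H, self.beta)
        self._w = np.vstack([self._w, w_new])
        return self.n_categories - 1

    def run(
        self, H_seq: np.ndarray, max_categories: int | None = None
    ) -> np.ndarray | None:
        """Present a sequence; returns assignments, or None if the category
        count ever exceeds ``max_categories`` (early abort)."""
        out = np.empty(len(H_seq), dtype=int)
        for i, H in enumerate(H_seq):
            out[i] = self.present(H)
            if max_categories is not None and self.n_categories > max_categories:
                return None
        return out


# ---------------------------------------------------------------------------
# spatial types and the supervised stage


def assign_type(pmap: PlaceMap, positions: np.ndarray,
                chunk: int = 1024) -> np.ndarray:
    """Type of each position: highest-rate cell firing >= A/2, else background.

    Ties go to the smallest cell id.  Accepts (2,) or (n, 2); returns int
    labels (cell id or BACKGROUND).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    out = np.full(n, BACKGROUND, dtype=int)
    if len(pmap) == 0:
        return out if n > 1 else out
    inv = 1.0 / pmap.sigmas**2
    r2_half = (pmap.half_max_radii) ** 2
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d2 = (
            (positions[a:b, None, 0] - pmap.centers[None, :, 0]) ** 2
            + (positions[a:b, None, 1] - pmap.centers[None, :, 1]) ** 2
        )
        # rate order is the order of -d2 * inv (A is common); argmax keeps
        # the smallest index on exact ties.  If any cell fires >= A/2 the
        # global rate argmax does too, so one covered test suffices.
        score = -d2 * inv[None, :]
        j = np.argmax(score, axis=1)
        covered = d2[np.arange(b - a), j] <= r2_half[j]
        out[a:b] = np.where(covered, j, BACKGROUND)
    return out


def type_members(
    pmap: PlaceMap, positions: np.ndarray, chunk: int = 1024
) -> list[np.ndarray]:
    """Lattice-point indices of each cell's type (its half-max field).

    A position belongs to cell i's type iff cell i fires >= A/2 there,
    i.e. lies within radius sigma_i*sqrt(ln 2) of its center.  Types
    overlap; a position may belong to several.  Order of indices follows
    the position order (row-major lattice).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    n = len(positions)
    r2_half = pmap.half_max_radii**2
    members: list[list[int]] = [[] for _ in range(len(pmap))]
    for a in range(0, n, chunk):
        b = min(a + chunk, n)
        d2 = (
            (positions[a:b, None, 0] - pmap.centers[None, :, 0]) ** 2
            + (positions[a:b, None, 1] - pmap.centers[None, :, 1]) ** 2
        )
        rows, cols = np.nonzero(d2 <= r2_half[None, :])
        for r, c in zip(rows, cols):
            members[c].append(a + int(r))
    return [np.array(m, dtype=int) for m in members]


def grid_population_input(
    united: list[GridParams], positions: np.ndarray
) -> np.ndarray:
    """Normalized input vectors: component j is grid cell j's rate in [0, 1]."""
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    out = np.empty((len(positions), len(united)))
    for j, gp in enumerate(united):
        out[:, j] = grid_rate(gp, positions)
    return np.clip(out, 0.0, 1.0)


def learn_vigilance(
    H_seq: np.ndarray,
    *,
    alpha: float = 0.001,
    beta: float = 1.0,
    rho_step: float = 0.001,
) -> float:
    """Largest rho (scanned downward from 1) at which the sequence forms
    exactly one category.

    Implements the supervised vigilance adjustment: a fresh fuzzy ART pass
    per trial rho, aborted as soon as a second category commits.
    """
    H_seq = np.atleast_2d(np.asarray(H_seq, dtype=float))
    if len(H_seq) == 0:
        raise ValueError("type has no sample locations")
    p = H_seq.shape[1] // 2
    n_levels = int(round(1.0 / rho_step))
    for k in range(n_levels + 1):
        rho = round(1.0 - k * rho_step, 10)
        art = FuzzyArt(dim=p, alpha=alpha, beta=beta, rho=rho)
        if art.run(H_seq, max_categories=1) is not None:
            return rho
    return 0.0


@dataclass(frozen=True)
class UnitedPlaceCell:
    id: int
    type_id: int  # supervising place-cell id, or BACKGROUND
    x: float
    y: float
    n_members: int
    in_sampling_region: bool


def generate_united_place_cells(
    pmap: PlaceMap,
    united: list[GridParams],
    arena: Arena,
    region_cell_mask: np.ndarray,
    *,
    spacing: float = 0.5,
    alpha: float = 0.001,
    beta: float = 1.0,
    rho_step: float = 0.001,
) -> tuple[list[UnitedPlaceCell], dict]:
    """Run the supervised fuzzy ART stage over the whole arena.

    Returns the united place cells and a summary dict with the learned
    per-supervisor vigilances and their mean.  Lattice locations are
    visited in row-major order (y outer, x inner), fixed across runs.
    """
    xs = np.arange(0.0, arena.width + spacing / 2, spacing)
    ys = np.arange(0.0, arena.height + spacing / 2, spacing)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()])  # y outer, x inner
    members = type_members(pmap, lattice)
    background_idx = np.flatnonzero(assign_type(pmap, lattice) == BACKGROUND)
    I = grid_population_input(united, lattice)
    H = complement_code(I)
    p = len(united)

    region_ids = np.flatnonzero(region_cell_mask)
    out: list[UnitedPlaceCell] = []
    rhos: dict[int, float] = {}
    skipped: list[int] = []
    uid = 0
    for cid in region_ids:
        idx = members[cid]
        if len(idx) == 0:
            skipped.append(int(cid))
            continue
        rho = learn_vigilance(H[idx], alpha=alpha, beta=beta,
                              rho_step=rho_step)
        rhos[int(cid)] = rho
        pts = lattice[idx]
        out.append(
            UnitedPlaceCell(
                id=uid, type_id=int(cid), x=float(pts[:, 0].mean()),
                y=float(pts[:, 1].mean()), n_members=len(idx),
                in_sampling_region=True,
            )
        )
        uid += 1
    if not rhos:
        raise ValueError("no supervisor type had sample locations")
    mean_rho = float(np.mean(list(rhos.values())))

    other_ids = [int(c) for c in np.flatnonzero(~np.asarray(region_cell_mask))]
    for cid in other_ids + [BACKGROUND]:
        idx = background_idx if cid == BACKGROUND else members[cid]
        if len(idx) == 0:
            continue
        art = FuzzyArt(dim=p, alpha=alpha, beta=beta, rho=mean_rho)
        assign = art.run(H[idx])
        pts = lattice[idx]
        for cat in range(art.n_categories):
            member = assign == cat
            out.append(
                UnitedPlaceCell(
                    id=uid, type_id=int(cid),
                    x=float(pts[member, 0].mean()),
                    y=float(pts[member, 1].mean()),
                    n_members=int(member.sum()),
                    in_sampling_region=False,
                )
            )
            uid += 1
    summary = {
        "vigilances": rhos,
        "mean_rho": mean_rho,
        "n_supervisors": len(rhos),
        "n_supervisors_skipped": len(skipped),
        "skipped_supervisors": skipped,
        "n_united_place_cells": len(out),
        "lattice_spacing": spacing,
    }
    return out, summary
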