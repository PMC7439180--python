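"""Binary-encoded genetic algorithm fitting grid parameters to a visual grid cell.

Each candidate united grid cell is a chromosome of 5*M bits encoding
(C, B, x0, y0, omega) linearly within their admissible ranges

    C in [0, 1] Hz,  B in [0, min(L1, L2)/2] m,
    x0 in [0, L1] m, y0 in [0, L2] m,  omega in [0, 2 pi] rad.

While the agent walks the arena, the (normalized) visual grid cell's rate
is recorded at every step that falls inside the GA *sampling region* — the
locations where some place cell both fires above half-max and projects a
weight above the threshold Psi to at least one trained visual grid cell.
Every K records close a generation: the fitness of each of the 2N parent +
offspring candidates is the sum of squared differences between the
candidate's three-cosine rate and the recorded visual rate at the K record
positions, and the N lowest-fitness candidates survive (elitist mu+lambda
selection, ties to the lower index).  The walk budget plays the role of
the stopping condition.

Because a visual grid cell's field is a quasi one-dimensional band along
one wall, the fit is degenerate up to a pi/6 rotation of the lattice; a
second fit with omega held at the free fit's direction plus pi/6 produces
the partner cell, giving 32 united grid cells for 4 taus x 4 walls x 2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .arena import Arena, random_walk
from .grid_model import GridParams, grid_rate_many
from .hebbian import VisualGridCell, visual_grid_rate
from .place_cells import PlaceMap

__all__ = [
    "GaConfig",
    "param_ranges",
    "decode",
    "random_population",
    "crossover",
    "mutate",
    "fitness",
    "sampling_region_mask",
    "sampling_region_cells",
    "sampling_grid_points",
    "ga_fit",
    "ga_optimize",
    "build_united_population",
    "GaFitResult",
]


@dataclass(frozen=True)
class GaConfig:
    n_pop: int = 100  # N
    m_bits: int = 10  # M, bits per parameter
    p_crossover: float = 0.6  # pc
    p_mutation: float = 0.1  # pm, expected bit flips per chromosome
    k_records: int = 500  # K, records per generation
    psi: float = 1.0  # sampling-region weight threshold
    budget: float = 1e5  # exploration time (s) per fit

    def __post_init__(self) -> None:
        if self.n_pop < 2 or self.m_bits < 1 or self.k_records < 1:
            raise ValueError("invalid GA configuration")
        if not (0 <= self.p_crossover <= 1 and 0 <= self.p_mutation <= 1):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def n_bits(self) -> int:
        return 5 * self.m_bits


def param_ranges(arena: Arena) -> np.ndarray:
    """(5, 2) array of (lo, hi) for (C, B, x0, y0, omega)."""
    return np.array(
        [
            [0.0, 1.0],
            [0.0, min(arena.width, arena.height) / 2.0],
            [0.0, arena.width],
            [0.0, arena.height],
            [0.0, 2.0 * np.pi],
        ]
    )


def decode(bits: np.ndarray, ranges: np.ndarray, m_bits: int) -> np.ndarray:
    """Decode chromosomes to parameter rows.

    Each M-bit block is read as an unsigned integer u (MSB first) and mapped
    linearly: lo + u / (2^M - 1) * (hi - lo).  Accepts a single chromosome
    (5M,) or a population (n, 5M); returns (5,) or (n, 5).
    """
    arr = np.asarray(bits)
    single = arr.ndim == 1
    arr = np.atleast_2d(arr)
    if arr.shape[1] != 5 * m_bits:
        raise ValueError("chromosome length must be 5*M")
    blocks = arr.reshape(len(arr), 5, m_bits)
    weights = 2 ** np.arange(m_bits - 1, -1, -1)
    u = blocks @ weights
    lo, hi = ranges[:, 0], ranges[:, 1]
    out = lo + u / (2**m_bits - 1) * (hi - lo)
    return out[0] if single else out


def random_population(
    n: int, n_bits: int, rng: np.random.Generator
) -> np.ndarray:
    return rng.integers(0, 2, size=(n, n_bits), dtype=np.uint8)


def crossover(
    p1: np.ndarray,
    p2: np.ndarray,
    pc: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Single-point crossover with probability pc, else copies.

    The cut is uniform over 0..len inclusive; the degenerate cuts swap or
    copy the parents.
    """
    p1 = np.asarray(p1)
    p2 = np.asarray(p2)
    if p1.shape != p2.shape:
        raise ValueError("parents differ in length")
    if rng.random() >= pc:
        return p1.copy(), p2.copy()
    cut = int(rng.integers(0, len(p1) + 1))
    c1 = np.concatenate([p1[:cut], p2[cut:]])
    c2 = np.concatenate([p2[:cut], p1[cut:]])
    return c1, c2


def mutate(
    chrom: np.ndarray, pm: float, rng: np.random.Generator
) -> np.ndarray:
    """Flip each bit independently with probability pm / len(chrom).

    Normalizing per chromosome keeps the expected number of flips equal to
    pm regardless of chromosome length.
    """
    chrom = np.asarray(chrom)
    flips = rng.random(chrom.shape) < pm / chrom.shape[-1]
    return np.where(flips, 1 - chrom, chrom).astype(chrom.dtype)


def _make_offspring(
    pop: np.ndarray, cfg: GaConfig, rng: np.random.Generator
) -> np.ndarray:
    order = rng.permutation(len(pop))
    children = np.empty_like(pop)
    for i in range(0, len(pop) - 1, 2):
        a, b = crossover(pop[order[i]], pop[order[i + 1]], cfg.p_crossover, rng)
        children[i], children[i + 1] = a, b
    if len(pop) % 2:
        children[-1] = pop[order[-1]].copy()
    return mutate(children, cfg.p_mutation, rng)


def fitness(
    param_array: np.ndarray,
    record_positions: np.ndarray,
    record_rates: np.ndarray,
) -> np.ndarray:
    """Sum of squared rate differences over the records, per candidate."""
    record_positions = np.asarray(record_positions, dtype=float)
    record_rates = np.asarray(record_rates, dtype=float)
    if len(record_positions) == 0:
        raise ValueError("empty record log")
    pred = grid_rate_many(np.atleast_2d(param_array), record_positions)
    out = np.sum((pred - record_rates[None, :]) ** 2, axis=1)
    return out


# ---------------------------------------------------------------------------
# sampling region


def sampling_region_cells(
    weight_vectors: list[np.ndarray], psi: float
) -> np.ndarray:
    """Boolean mask of place cells whose weight exceeds Psi in any vector."""
    strong = np.zeros_like(np.asarray(weight_vectors[0]), dtype=bool)
    for E in weight_vectors:
        strong |= np.asarray(E) > psi
    return strong


def sampling_region_mask(
    positions: np.ndarray,
    pmap: PlaceMap,
    weight_vectors: list[np.ndarray],
    psi: float,
    chunk: int = 2048,
    member_ids: np.ndarray | None = None,
) -> np.ndarray:
    """True where some above-threshold cell fires >= A/2.

    A cell fires above half-max exactly within radius sigma*sqrt(ln 2) of
    its center, so the region is the union of the half-max disks of the
    cells whose weight exceeds Psi in at least one trained vector.  With
    ``member_ids`` the region is restricted to the disks of those cells
    (used per visual-grid-cell fit).
    """
    positions = np.atleast_2d(np.asarray(positions, dtype=float))
    strong = sampling_region_cells(weight_vectors, psi)
    if member_ids is not None:
        keep = np.zeros_like(strong)
        keep[np.asarray(member_ids, dtype=int)] = True
        strong &= keep
    centers = pmap.centers[strong]
    r2 = (pmap.half_max_radii[strong]) ** 2
    out = np.zeros(len(positions), dtype=bool)
    if len(centers) == 0:
        return out
    for a in range(0, len(positions), chunk):
        b = min(a + chunk, len(positions))
        d2 = (
            (positions[a:b, None, 0] - centers[None, :, 0]) ** 2
            + (positions[a:b, None, 1] - centers[None, :, 1]) ** 2
        )
        out[a:b] = np.any(d2 <= r2[None, :], axis=1)
    return out


def sampling_grid_points(
    pmap: PlaceMap,
    weight_vectors: list[np.ndarray],
    psi: float,
    arena: Arena,
    spacing: float = 0.5,
    member_ids: np.ndarray | None = None,
) -> np.ndarray:
    """Lattice points (row-major, y outer) that lie in the sampling region.

    Used to normalize a visual grid cell ("maximum firing rate in the
    sampling region is 1 Hz"; restricted to its members via ``member_ids``)
    and, unrestricted, as the supervised-ART sample set.
    """
    xs = np.arange(0.0, arena.width + spacing / 2, spacing)
    ys = np.arange(0.0, arena.height + spacing / 2, spacing)
    gy, gx = np.meshgrid(ys, xs, indexing="ij")
    pts = np.column_stack([gx.ravel(), gy.ravel()])
    mask = sampling_region_mask(pts, pmap, weight_vectors, psi,
                                member_ids=member_ids)
    return pts[mask]


# ---------------------------------------------------------------------------
# the generational loop


@dataclass
class GaFitResult:
    params: GridParams
    best_fitness: list[float] = field(default_factory=list)
    n_generations: int = 0
    n_records: int = 0


def _strip_walk(
    arena: Arena,
    boundary: str,
    width: float,
    speed: float,
    budget: float,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Walk confined to a strip of ``width`` along one wall.

    Realizes the near-boundary exploration of the fitting stage: the walk
    runs in a sub-arena of the strip's dimensions and is mirrored onto the
    far walls when needed.
    """
    if boundary in ("y=0", "y=L2"):
        sub = Arena(arena.width, width, d_max=arena.d_max,
                    field_const=arena.field_const)
    else:
        sub = Arena(width, arena.height, d_max=arena.d_max,
                    field_const=arena.field_const)
    walk = random_walk(sub, speed, budget, dt, rng=rng)
    p = walk.positions
    if boundary == "y=L2":
        p[:, 1] = arena.height - p[:, 1]
    elif boundary == "x=L1":
        p[:, 0] = arena.width - p[:, 0]
    return p


def _member_strip_width(
    vgc: VisualGridCell,
    pmap: PlaceMap,
    arena: Arena,
    weight_vectors: list[np.ndarray],
    psi: float,
    min_width: float,
) -> float:
    """Extent of the cell's part of the sampling region from its wall."""
    strong = sampling_region_cells(weight_vectors, psi)
    keep = np.zeros_like(strong)
    keep[np.asarray(vgc.member_ids, dtype=int)] = True
    sel = strong & keep
    if not np.any(sel):
        raise ValueError(
            f"no member of {vgc.boundary} exceeds the weight threshold"
        )
    c = pmap.centers[sel]
    r = pmap.half_max_radii[sel]
    if vgc.boundary == "y=0":
        dist = c[:, 1]
    elif vgc.boundary == "y=L2":
        dist = arena.height - c[:, 1]
    elif vgc.boundary == "x=0":
        dist = c[:, 0]
    else:
        dist = arena.width - c[:, 0]
    return float(np.clip((dist + r).max(), min_width, arena.d_max))


def ga_fit(
    vgc: VisualGridCell,
    pmap: PlaceMap,
    arena: Arena,
    weight_vectors: list[np.ndarray],
    cfg: GaConfig,
    *,
    speed: float = 2.0,
    dt: float = 1.0,
    seed: int | None = None,
    fixed_omega: float | None = None,
) -> GaFitResult:
    """Fit GridParams to one visual grid cell.

    The agent explores the strip along the cell's wall for ``cfg.budget``
    seconds; records are taken at steps inside the cell's part of the
    sampling region and consumed K at a time, one generation per batch.
    With ``fixed_omega`` the direction is held fixed (not evolved).
    """
    if vgc.norm is None:
        raise ValueError("visual grid cell not normalized")
    rng = np.random.default_rng(seed)
    width = _member_strip_width(vgc, pmap, arena, weight_vectors, cfg.psi,
                                min_width=1.5 * speed * dt)
    positions = _strip_walk(arena, vgc.boundary, width, speed, cfg.budget,
                            dt, rng)
    mask = sampling_region_mask(positions, pmap, weight_vectors,
                                cfg.psi, member_ids=vgc.member_ids)
    record_pos = positions[mask]
    g_visual = visual_grid_rate(vgc, pmap, record_pos)
    return ga_optimize(record_pos, g_visual, param_ranges(arena), cfg, rng,
                       fixed_omega=fixed_omega)


def ga_optimize(
    record_pos: np.ndarray,
    record_rates: np.ndarray,
    ranges: np.ndarray,
    cfg: GaConfig,
    rng: np.random.Generator,
    *,
    fixed_omega: float | None = None,
) -> GaFitResult:
    """Generational loop over a stream of (position, target-rate) records.

    Records are consumed K at a time; every batch closes one generation
    (initialize N random chromosomes; produce N offspring by crossover and
    mutation; evaluate all 2N candidates on the batch; keep the N lowest
    fitness, ties to the lower index).  Returns the best candidate seen.
    """
    record_pos = np.asarray(record_pos, dtype=float)
    record_rates = np.asarray(record_rates, dtype=float)
    n_gen = len(record_pos) // cfg.k_records
    if n_gen < 1:
        raise ValueError(
            "exploration budget too small to fill one K-record generation"
        )
    pop = random_population(cfg.n_pop, cfg.n_bits, rng)
    best_hist: list[float] = []
    best_fit = np.inf
    best_params: np.ndarray | None = None
    for g in range(n_gen):
        offspring = _make_offspring(pop, cfg, rng)
        combined = np.vstack([pop, offspring])
        params = np.atleast_2d(decode(combined, ranges, cfg.m_bits))
        if fixed_omega is not None:
            params[:, 4] = fixed_omega
        params[:, 1] = np.maximum(params[:, 1], 1e-9)  # B=0 chromosome guard
        sl = slice(g * cfg.k_records, (g + 1) * cfg.k_records)
        fit = fitness(params, record_pos[sl], record_rates[sl])
        order = np.argsort(fit, kind="stable")
        pop = combined[order[: cfg.n_pop]]
        if fit[order[0]] < best_fit:
            best_fit = float(fit[order[0]])
            best_params = params[order[0]].copy()
        best_hist.append(float(fit[order[0]]))
    assert best_params is not None
    C, B, x0, y0, om = best_params
    gp = GridParams(max_rate=C, spacing=B, phase_x=x0, phase_y=y0,
                    orientation=om)
    return GaFitResult(
        params=gp,
        best_fitness=best_hist,
        n_generations=n_gen,
        n_records=n_gen * cfg.k_records,
    )


TABLE_BOUNDARY_ORDER = ("y=0", "y=L2", "x=0", "x=L1")


def build_united_population(
    vgcs_by_tau: dict[int, list[VisualGridCell]],
    pmap: PlaceMap,
    arena: Arena,
    weight_vectors: list[np.ndarray],
    cfg: GaConfig,
    *,
    speed: float = 2.0,
    dt: float = 1.0,
    seed_fn=None,
) -> list[dict]:
    """Fit all visual grid cells twice (free, then omega + pi/6 fixed).

    Returns 32 entries (for 4 taus x 4 walls) ordered boundary-major in the
    wall order y=0, y=L2, x=0, x=L1, tau ascending within a wall, free fit
    before offset fit.  Each entry is a dict with boundary, tau, offset flag
    and the fitted GridParams.
    """
    if seed_fn is None:
        seed_fn = lambda i: None  # noqa: E731
    taus = sorted(vgcs_by_tau)
    out: list[dict] = []
    i_fit = 0
    for boundary in TABLE_BOUNDARY_ORDER:
        for tau in taus:
            vgc = next(
                v for v in vgcs_by_tau[tau] if v.boundary == boundary
            )
            free = ga_fit(
                vgc, pmap, arena, weight_vectors, cfg,
                speed=speed, dt=dt, seed=seed_fn(i_fit),
            )
            i_fit += 1
            omega2 = float(np.mod(free.params.orientation + np.pi / 6.0,
                                  2.0 * np.pi))
            offset = ga_fit(
                vgc, pmap, arena, weight_vectors, cfg,
                speed=speed, dt=dt, seed=seed_fn(i_fit),
                fixed_omega=omega2,
            )
            i_fit += 1
            out.append({"boundary": boundary, "tau": tau, "offset": False,
                        "fit": free})
            out.append({"boundary": boundary, "tau": tau, "offset": True,
                        "fit": offset})
    return out
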