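# Methods

This note documents the model implemented by `unitedcells`, the choices
made where the design was genuinely open, and what the simulations do and
do not establish. Symbols follow the package API; defaults are the
canonical simulation conditions (`unitedcells.default_config()`).

## Arena and exploration

The agent forages in a closed rectangle `[0, L1] x [0, L2]` (default
80 x 60 m) at constant speed `v = 2 m/s`. The walk is a correlated random
walk: the heading diffuses with turning noise `turn_sigma` (rad/sqrt(s))
and the path reflects specularly off the walls (implemented by billiard
unfolding, so step lengths are exact). `turn_sigma = 0.2` gives a heading
persistence time of `1/turn_sigma^2 = 25 s` — longer than every Hebbian
delay used (4–7 s), so the displacement over one delay is close to `v*tau`
— while keeping long-run occupancy near uniform (coefficient of variation
of 10x10 bin counts ~0.06–0.08 over 1e5 s). A much noisier walk (e.g.
0.5 rad per second-step) smears the delayed-correlation ring that drives
the weight patterning below; this was checked directly on the spectrum of
the empirical growth operator.

Two walk variants are used. Stage 1 explores the whole arena uniformly
(sampled at `dt = 1 s`, which is also the recruitment-check interval).
Stage 2 uses a walk confined to the boundary frame of width `D` — the zone
that contains every place cell — implemented as a walk in an unrolled
perimeter strip wrapped back onto the rectangle. Walking the cell-free
center would only dilute the visit rate that the weight dynamics integrate
over; distances are slightly distorted where the strip turns a corner,
which has no visible effect on the learned weights.

## Visual place cells

A place field is `R_i = A exp(-r^2 / sigma_i^2)` with peak `A = 10 Hz`;
`sigma_i` is a width parameter (the half-max radius is
`sigma_i sqrt(ln 2)`). Recruitment adds a cell at the agent's location
whenever all existing rates are below `A/2` and the wall distance is at
most `D = 20 m`; the new width follows the geometric interpolation
`sigma(d) = l_min^((L-d)/(L-1)) l_max^((d-1)/(L-1))` with `l_min = 1 m`,
`l_max = 15 m`, `L = 30`. For `d < 1 m` the formula is evaluated as
written (widths slightly below `l_min`); no clamp is applied. The
`A/2`-coverage condition is evaluated as a half-max-disk test, which is
algebraically identical and avoids exponentials in the hot loop.

With these conditions a 1e5 s walk recruits ~1420–1440 cells, saturating
slowly (dense uniform sampling of the same rule yields ~1520). Checking
recruitment more often than once per second overshoots this density and
was not adopted.

## Delayed-Hebbian visual grid cells

One downstream cell per delay `tau` in {4, 5, 6, 7} s receives all place
cells through weights `E_n`:

    eta^-1 dE_n/dt = -E_n + [R_n(t) - h R_n(t - tau)] G(t) + S,
    G(t) = sum_i E_i R_i(t),

with `eta = 5e-6`, `h = 5`, `S = 7`. After every update the competitive
restriction is applied: weights below `Th_down = 0` are clipped up, and if
any weight exceeds `Th_up = 5` the *same amount* `max(E) - Th_up` is
subtracted from every weight ("equally scaled down"). Subtractive
enforcement matters: it makes the competition winner-take-all and drives
weights toward the bounds, whereas a divisive rescale leaves graded,
low-contrast weights. Initial weights are i.i.d. uniform on
`[Th_down, Th_up]` so competition is active from the first step; the final
state is insensitive to this choice (constant and zero initializations
converge to the same attractor).

The rule is integrated at a 0.1 s simulation step with `eta` applied per
update and `tau` counted in seconds (a ring buffer of `tau/0.1` past rate
vectors). The integration step is a genuine model parameter here, because
the per-update learning rate fixes the learning *per unit time* at
`eta/dt`: at 1 s steps the band-forming instability of the delayed
correlation (center excitation minus an `h`-weighted ring at radius
`v*tau`) amplifies only ~e^1.5 over the run and no pattern emerges, while
at 0.1 s steps the weights develop clear bands along each wall. The
fastest-growing mode of the kernel sits near wavelength
`2 pi v tau / 3.83 ≈ 1.64 v tau`, and the measured band periods grow from
~12 m at `tau = 4` to ~20 m at `tau = 7`, with in-window spectral power
20–250x the median. Cells more than ~7 m from a wall end below the weight
threshold `Psi = 1` (the delayed term depresses them on every pass), which
is what later defines the sampling region.

Place cells are partitioned by nearest wall (ties in the order x=0, x=L1,
y=0, y=L2); each wall's sub-population with its weight sub-vector is one
*visual grid cell*, normalized so its maximum rate over its own part of
the sampling region (0.5 m grid) is 1 Hz.

## United grid cells (GA fit)

The three-cosine field

    G(r) = C * 2/3 * [ 1/3 sum_{d=1..3} cos( 4 pi / (sqrt(3) B) k_d . (r - phi) ) + 1/2 ],
    k_d = (cos(omega + (2d-1) pi/3), sin(omega + (2d-1) pi/3)),

lies in `[0, C]`, peaks at exactly `C` on a triangular lattice of spacing
`B`, and is the unique frequency normalization with those two properties.
Parameters are encoded in a `5M`-bit chromosome (`M = 10`), decoded
linearly within `C in [0,1]`, `B in [0, min(L1,L2)/2]`, `x0 in [0,L1]`,
`y0 in [0,L2]`, `omega in [0, 2pi]`.

Per fit, the agent explores the strip along the cell's wall (width = the
extent of the cell's strong members' half-max disks, capped at `D`) for
1e5 s, sampled at the 0.1 s simulation step. Records are taken at steps
inside the cell's part of the sampling region — locations where one of
its *member* cells fires above `A/2` with weight above `Psi`. Restricting
records to the cell's own members is essential: against the union region
of all four walls, three quarters of the records are walls where the cell
is silent and the fit collapses to near-constant low-`C` solutions.

Every `K = 500` records close a generation: parents are paired at random;
single-point crossover fires with `pc = 0.6` (cut uniform over 0..len
inclusive, so the degenerate cuts swap or copy); each bit then flips with
probability `pm / (5M)` so the expected flips per chromosome equal
`pm = 0.1`; all `2N` parents and offspring (`N = 100`) are scored by the
sum of squared rate differences over the batch and the `N` lowest survive
(ties to the lower index). `K` is a free choice (500 balances fitness
stability against generation count, ~1000 generations per fit); the
exploration budget is the stopping condition. Each of the 32 fits uses an
independently derived walk seed.

Because a quasi one-dimensional band fixes the lattice only up to a
`pi/6` rotation, each visual grid cell is fitted twice — once free, once
with `omega` held at the free fit's direction plus `pi/6` — giving 32
united grid cells (4 taus x 4 walls x 2), reported boundary-major in the
order y=0, y=L2, x=0, x=L1. On synthetic fields sampled in a 10 m band
the GA recovers `B` within 5%, `omega` within 0.05 rad modulo `pi/3`, and
the whole-arena rate map to correlation > 0.95 (the generator is the test
oracle).

## United place cells (supervised fuzzy ART)

Inputs are the 32 grid-cell rates at a location, complement-coded
(`|H| = p` always). Choice, match and fast learning (`alpha = 0.001`,
`beta = 1`) follow the standard fuzzy ART equations; the implementation
replaces the sequential select-test-reset loop by the equivalent "highest
choice value among the vigilance-passing nodes" rule (both quantities are
fixed during one presentation), verified input-for-input against a
literal step-by-step reference.

Space is divided into overlapping *types*: each place cell's half-max
field is one type, and locations covered by no field form the background
type. Locations are the 0.5 m lattice in row-major order (y outer), a
fixed order since ART is order-sensitive. For each type inside the
sampling region (cells with weight > `Psi`; ~1100 of ~1430), the vigilance
is lowered from 1.0 in steps of 0.001 — a fresh ART pass per trial,
aborted as soon as a second category commits — until the type's inputs
form exactly one category; that type contributes one united place cell at
its points' centroid. All remaining types (including the background) are
clustered at the mean learned vigilance; every resulting category is a
united place cell. Note that the category count is *not* strictly
monotone in the vigilance (committed-box order effects produce occasional
dips, demonstrated in the test suite), which is why the search scans every
step instead of bisecting.

## Problem sizes and runtime

The canonical run uses 1e5 s of exploration per stage (1e6 simulation
steps at 0.1 s; 1e5 recruitment checks), four delays, 32 GA fits of ~1000
generations, and a 161 x 121 ART lattice; it completes in ~8 minutes on
one core (the weight-training loop is JIT-compiled when numba is present).
The test suite runs this once and otherwise uses a geometrically reduced
fixture (20 x 15 m, 1e4 s, N = 20, K = 100, 0.125 m lattice) that
preserves every structural property at ~1/50 the cost.

## What the generator does and does not emulate

The synthetic exploration is a constant-speed correlated walk with
uniform coverage — there is no thigmotaxis, resting, or speed modulation,
and the "visual" drive is reduced to exact wall distances. Passing tests
therefore show that the *model* behaves as described under its own stated
conditions, not that a real agent's sensory stream would produce these
counts. Head-direction and speed cells, non-rectangular arenas, place
field remapping, and grid-module spacing ratios are all outside the
model; the fitted spacings here carry no module structure.

## Known limitations

- The weight bands along each wall are lower-contrast than the idealized
  binary pattern the model aims at: the in-region band ends near 7 m
  instead of ~6.5 m, leaving the out-of-region cell count ~20% low
  (~320 vs ~399) and the mean learned vigilance ~0.06 high (~0.88 vs
  ~0.825) at the canonical scale, since slightly larger fitted spacings
  mean less grid-rate variation across a type. Both quantities are
  asserted at their strict tolerances in `tests/test_acceptance.py` and
  currently fail there by those margins; all other headline quantities
  pass.
- The fitted `B` values inherit the band degeneracy: only the pair
  (free, +pi/6) together pins the lattice family, and individual fitted
  parameter values are run-specific.
- The gridness score uses a fixed annulus (first zero crossing to 2.5x
  that radius) and linear-interpolation rotations; it is a diagnostic,
  not a publication-grade gridness pipeline.
- The frame walk distorts distances at the four corners of the strip by
  up to the strip width over the corner arc; none of the learned
  quantities measurably depend on this.
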