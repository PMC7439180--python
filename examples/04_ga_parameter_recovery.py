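"""Recover grid parameters from band-restricted samples with the GA.

A known grid field is sampled only inside a 10 m strip along one wall —
the observability regime of the pipeline, where a boundary visual grid
cell serves as the sample of a whole-arena grid cell.  The binary-encoded
GA (N=100, M=10 bits/parameter, single-point crossover, elitist selection)
recovers spacing and direction from those samples alone.
"""

import numpy as np

from unitedcells import (
    Arena, GaConfig, GridParams, ga_optimize, grid_rate, param_ranges, rate_map,
)

arena = Arena(80.0, 60.0)
true = GridParams(max_rate=1.0, spacing=12.0, phase_x=30.0, phase_y=4.0,
                  orientation=0.4)
rng = np.random.default_rng(5)
positions = np.column_stack(
    [rng.uniform(0, arena.width, 60_000), rng.uniform(0, 10.0, 60_000)]
)
records = grid_rate(true, positions)

result = ga_optimize(positions, records, param_ranges(arena), GaConfig(), rng)
fit = result.params

corr = np.corrcoef(
    rate_map(true, arena, 0.5).values.ravel(),
    rate_map(fit, arena, 0.5).values.ravel(),
)[0, 1]
d_om = (fit.orientation - true.orientation) % (np.pi / 3)
d_om = min(d_om, np.pi / 3 - d_om)
print(f"{result.n_generations} generations, "
      f"final best fitness {result.best_fitness[-1]:.3g}")
print(f"spacing: true 12.0 m, fitted {fit.spacing:.2f} m")
print(f"direction: off by {d_om:.4f} rad modulo the pi/3 lattice symmetry")
print(f"whole-arena rate-map correlation: {corr:.3f}")
# The strip constrains the lattice enough to pin B and omega; the phase is
# recovered modulo lattice translations, so the map correlation is the
# honest overall score.
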