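"""Run the four-stage pipeline end to end at reduced scale.

Stage 1 recruits visual place cells along a uniform foraging walk; stage 2
learns delayed-Hebbian place-to-grid weights for each update interval tau;
stage 3 fits two whole-arena grid cells per boundary visual grid cell with
the GA (free direction, then direction + pi/6); stage 4 turns the grid
population code into united place cells with supervised fuzzy ART.

At the canonical scale (80 x 60 m, 1e5 s) the same call reproduces the
full-size simulation; the 0.25 fixture finishes in about a minute.
"""

import json
from pathlib import Path

from unitedcells import make_fixture
from unitedcells.pipeline import run_all

out = Path("runs/example_fixture")
cfg = make_fixture(scale=0.25, seed=11)
summary = run_all(cfg, out)

manifest = json.loads((out / "manifest.json").read_text())
print(f"stage 1: {manifest['stage1']['n_place_cells']} visual place cells")
print(f"stage 3: {manifest['stage3']['n_united_grid_cells']} united grid cells")
print(f"stage 4: {summary['n_supervisors']} supervisor types, "
      f"mean vigilance {summary['mean_rho']:.4f}")
print(f"         {summary['n_united_place_cells']} united place cells")
print(f"artifacts in {out}/ (CSV + JSON; see manifest.json)")
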