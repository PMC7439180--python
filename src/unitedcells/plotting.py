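"""Optional matplotlib renderings of pipeline artifacts.

Produces the four standard panels from a completed run directory: the
place-cell distribution with half-max field circles, the learned weight
maps per tau, one united-grid-cell rate map, and the united place cell
distribution.  Imported lazily so matplotlib stays an optional extra.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .arena import Arena
from .config import RunConfig
from .grid_model import GridParams, rate_map
from .pipeline import arena_from_config
from .place_cells import HALF_MAX_FACTOR


def render_run(cfg: RunConfig, out_dir: Path) -> list[Path]:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    arena = arena_from_config(cfg)
    written: list[Path] = []

    pc = pd.read_csv(out_dir / "place_cells.csv")
    fig, ax = plt.subplots(figsize=(8, 6))
    ax.plot(pc.x, pc.y, "r.", ms=3)
    for row in pc.itertuples(index=False):
        ax.add_patch(
            plt.Circle((row.x, row.y), row.sigma * HALF_MAX_FACTOR,
                       fill=False, color="b", lw=0.3)
        )
    ax.set(xlim=(0, arena.width), ylim=(0, arena.height), aspect="equal",
           title=f"{len(pc)} visual place cells (half-max fields)")
    p = out_dir / "place_cells.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    taus = list(cfg.tau_list)
    fig, axes = plt.subplots(1, len(taus), figsize=(5 * len(taus), 4))
    for ax, tau in zip(np.atleast_1d(axes), taus):
        E = pd.read_csv(out_dir / f"weights_tau{tau}.csv").E
        sc = ax.scatter(pc.x, pc.y, c=E, s=6, cmap="jet")
        ax.set(aspect="equal", title=f"weights, tau={tau}")
        fig.colorbar(sc, ax=ax, shrink=0.7)
    p = out_dir / "weights.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    ug = pd.read_csv(out_dir / "united_grid_cells.csv")
    row = ug.iloc[0]
    gp = GridParams(max_rate=row.max_rate, spacing=row.spacing,
                    phase_x=row.phase_x, phase_y=row.phase_y,
                    orientation=row.direction)
    rm = rate_map(gp, arena, 0.5)
    fig, ax = plt.subplots(figsize=(8, 6))
    im = ax.imshow(rm.values, origin="lower", cmap="jet",
                   extent=(0, arena.width, 0, arena.height))
    ax.set_title(
        f"united grid cell ({row.boundary}, tau={row.tau}): "
        f"B={row.spacing:.1f} m"
    )
    fig.colorbar(im, ax=ax, shrink=0.8)
    p = out_dir / "united_grid_cell.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)

    up = pd.read_csv(out_dir / "united_place_cells.csv")
    fig, ax = plt.subplots(figsize=(8, 6))
    for flag, color in [(True, "b"), (False, "r")]:
        sel = up[up.in_sampling_region == flag]
        ax.plot(sel.center_x, sel.center_y, f"{color}.", ms=3)
    ax.set(xlim=(0, arena.width), ylim=(0, arena.height), aspect="equal",
           title=f"{len(up)} united place cells "
                 "(blue: sampling region, red: outside)")
    p = out_dir / "united_place_cells.png"
    fig.savefig(p, dpi=120)
    plt.close(fig)
    written.append(p)
    return written
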