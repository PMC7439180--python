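"""End-to-end pipeline: place cells -> grid weights -> united grid cells -> united place cells.

Each stage reads its predecessors' persisted artifacts from the working
directory, writes its own CSV/JSON outputs, and updates ``manifest.json``,
so any later stage can be re-run without recomputing earlier ones.  All
randomness derives from the run seed through per-stage ``SeedSequence``
children, making every stage independently reproducible.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .arena import Arena, Trajectory, frame_walk, random_walk
from .config import RunConfig
from .fuzzy_art import generate_united_place_cells
from .ga_fit import (
    GaConfig,
    build_united_population,
    sampling_grid_points,
    sampling_region_cells,
)
from .grid_model import GridParams
from .hebbian import (
    GridWeights,
    HebbianParams,
    split_by_boundary,
    set_normalization,
    train_weights,
)

log = logging.getLogger("unitedcells")

__all__ = [
    "arena_from_config",
    "run_stage1",
    "run_stage2",
    "run_stage3",
    "run_stage4",
    "run_all",
    "StageError",
]


class StageError(RuntimeError):
    """A stage's predecessor artifact is missing."""


def arena_from_config(cfg: RunConfig) -> Arena:
    return Arena(width=cfg.width, height=cfg.height, d_max=cfg.d_max,
                 field_const=cfg.field_const)


def _sub_seed(seed: int, stage: int, item: int = 0) -> int:
    """Deterministic per-stage, per-item child seed below 2**31."""
    ss = np.random.SeedSequence([seed, stage, item])
    return int(ss.generate_state(1)[0] % (2**31))


def _update_manifest(out_dir: Path, stage: str, entry: dict) -> None:
    path = out_dir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {}
    manifest[stage] = entry
    path.write_text(json.dumps(manifest, indent=1))


# ---------------------------------------------------------------------------


def run_stage1(cfg: RunConfig, out_dir: str | Path):
    """Exploration walk + place-cell recruitment; writes place_cells.csv."""
    from .place_cells import run_recruitment

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    arena = arena_from_config(cfg)
    walk = random_walk(
        arena, cfg.speed, cfg.duration, cfg.dt,
        seed=_sub_seed(cfg.seed, 1), turn_sigma=cfg.turn_sigma,
    )
    pmap = run_recruitment(
        walk, arena, l_min=cfg.l_min, l_max=cfg.l_max,
        max_rate=cfg.max_rate, check_interval=cfg.dt,
    )
    walk.to_csv(out_dir / "trajectory.csv")
    pmap.to_csv(out_dir / "place_cells.csv")
    cfg.to_yaml(out_dir / "config.yaml")
    dtime = time.time() - t0
    log.info("stage1: %d place cells in %.1f s", len(pmap), dtime)
    _update_manifest(
        out_dir, "stage1",
        {"place_cells": "place_cells.csv", "trajectory": "trajectory.csv",
         "n_place_cells": len(pmap), "seconds": round(dtime, 2),
         "seed": cfg.seed},
    )
    return pmap, walk


def _load_stage1(cfg: RunConfig, out_dir: Path):
    from .place_cells import PlaceMap

    pc = out_dir / "place_cells.csv"
    tr = out_dir / "trajectory.csv"
    if not pc.exists() or not tr.exists():
        raise StageError("stage 1 artifacts missing; run stage1 first")
    return PlaceMap.from_csv(pc), Trajectory.from_csv(tr)


def run_stage2(cfg: RunConfig, out_dir: str | Path):
    """Delayed-Hebbian training of one weight vector per tau.

    The training walk circulates through the boundary frame of width D
    (where all place cells live) at the fine simulation step; the same
    walk is reused across the tau values for comparability.
    """
    out_dir = Path(out_dir)
    pmap, _ = _load_stage1(cfg, out_dir)
    t0 = time.time()
    arena = arena_from_config(cfg)
    width = min(cfg.d_max, min(cfg.width, cfg.height) / 2)
    walk = frame_walk(
        arena, width, cfg.speed, cfg.duration, cfg.hebb_dt,
        seed=_sub_seed(cfg.seed, 2, 0), turn_sigma=cfg.turn_sigma,
    )
    params = HebbianParams(eta=cfg.eta, h=cfg.h, s_const=cfg.s_const,
                           th_down=cfg.th_down, th_up=cfg.th_up)
    weights: dict[int, GridWeights] = {}
    for i, tau in enumerate(cfg.tau_list):
        rng = np.random.default_rng(_sub_seed(cfg.seed, 2, 1 + i))
        gw = train_weights(walk, pmap, tau, params, rng=rng)
        weights[tau] = gw
        pd.DataFrame(
            {"place_cell_id": np.arange(len(gw.E)), "E": gw.E}
        ).to_csv(out_dir / f"weights_tau{tau}.csv", index=False)
        log.info("stage2: tau=%d trained, max weight %.3f", tau, gw.E.max())
    meta = {"tau_list": list(cfg.tau_list), "eta": cfg.eta, "h": cfg.h,
            "s_const": cfg.s_const, "th_down": cfg.th_down,
            "th_up": cfg.th_up, "seed": cfg.seed}
    (out_dir / "weights_meta.json").write_text(json.dumps(meta, indent=1))
    dtime = time.time() - t0
    _update_manifest(
        out_dir, "stage2",
        {"weights": {str(t): f"weights_tau{t}.csv" for t in cfg.tau_list},
         "seconds": round(dtime, 2)},
    )
    return weights


def _load_stage2(cfg: RunConfig, out_dir: Path) -> dict[int, GridWeights]:
    params = HebbianParams(eta=cfg.eta, h=cfg.h, s_const=cfg.s_const,
                           th_down=cfg.th_down, th_up=cfg.th_up)
    weights = {}
    for tau in cfg.tau_list:
        path = out_dir / f"weights_tau{tau}.csv"
        if not path.exists():
            raise StageError(f"stage 2 artifact {path.name} missing")
        E = pd.read_csv(path)["E"].to_numpy()
        weights[tau] = GridWeights(E=E, tau=tau, params=params)
    return weights


def run_stage3(cfg: RunConfig, out_dir: str | Path):
    """GA fitting of 2 united grid cells per visual grid cell."""
    out_dir = Path(out_dir)
    pmap, _ = _load_stage1(cfg, out_dir)
    weights = _load_stage2(cfg, out_dir)
    t0 = time.time()
    arena = arena_from_config(cfg)
    ga_cfg = GaConfig(
        n_pop=cfg.ga_n_pop, m_bits=cfg.ga_m_bits, p_crossover=cfg.ga_pc,
        p_mutation=cfg.ga_pm, k_records=cfg.ga_k_records, psi=cfg.ga_psi,
        budget=cfg.ga_budget,
    )
    weight_vectors = [weights[t].E for t in cfg.tau_list]
    vgcs_by_tau = {}
    for tau in cfg.tau_list:
        vgcs = split_by_boundary(pmap, weights[tau], arena)
        for v in vgcs:
            # normalization grid: the cell's own part of the sampling region
            pts = sampling_grid_points(
                pmap, weight_vectors, ga_cfg.psi, arena, cfg.art_spacing,
                member_ids=v.member_ids,
            )
            set_normalization(v, pmap, pts)
        vgcs_by_tau[tau] = vgcs
    entries = build_united_population(
        vgcs_by_tau, pmap, arena, weight_vectors, ga_cfg,
        speed=cfg.speed, dt=cfg.hebb_dt,
        seed_fn=lambda i: _sub_seed(cfg.seed, 3, i),
    )
    rows = []
    for e in entries:
        gp = e["fit"].params
        rows.append(
            {
                "boundary": e["boundary"], "tau": e["tau"],
                "offset": e["offset"], "spacing": gp.spacing,
                "phase_x": gp.phase_x, "phase_y": gp.phase_y,
                "max_rate": gp.max_rate, "direction": gp.orientation,
                "final_fitness": e["fit"].best_fitness[-1],
                "n_generations": e["fit"].n_generations,
            }
        )
    df = pd.DataFrame(rows)
    df.to_csv(out_dir / "united_grid_cells.csv", index=False)
    dtime = time.time() - t0
    log.info("stage3: %d united grid cells in %.1f s", len(df), dtime)
    _update_manifest(
        out_dir, "stage3",
        {"united_grid_cells": "united_grid_cells.csv",
         "n_united_grid_cells": len(df), "seconds": round(dtime, 2)},
    )
    return entries


def load_united_grid_cells(out_dir: Path) -> list[GridParams]:
    path = Path(out_dir) / "united_grid_cells.csv"
    if not path.exists():
        raise StageError("stage 3 artifact united_grid_cells.csv missing")
    df = pd.read_csv(path)
    return [
        GridParams(
            max_rate=r.max_rate, spacing=r.spacing, phase_x=r.phase_x,
            phase_y=r.phase_y, orientation=r.direction,
        )
        for r in df.itertuples(index=False)
    ]


def run_stage4(cfg: RunConfig, out_dir: str | Path):
    """Supervised fuzzy ART: vigilance learning + united place cells."""
    out_dir = Path(out_dir)
    pmap, _ = _load_stage1(cfg, out_dir)
    weights = _load_stage2(cfg, out_dir)
    united = load_united_grid_cells(out_dir)
    t0 = time.time()
    arena = arena_from_config(cfg)
    weight_vectors = [weights[t].E for t in cfg.tau_list]
    region_mask = sampling_region_cells(weight_vectors, cfg.ga_psi)
    cells, summary = generate_united_place_cells(
        pmap, united, arena, region_mask,
        spacing=cfg.art_spacing, alpha=cfg.art_alpha, beta=cfg.art_beta,
        rho_step=cfg.art_rho_step,
    )
    pd.DataFrame(
        [
            {"id": c.id, "type": c.type_id, "center_x": c.x, "center_y": c.y,
             "n_members": c.n_members,
             "in_sampling_region": c.in_sampling_region}
            for c in cells
        ]
    ).to_csv(out_dir / "united_place_cells.csv", index=False)
    pd.DataFrame(
        {"supervisor_id": list(summary["vigilances"].keys()),
         "rho": list(summary["vigilances"].values())}
    ).to_csv(out_dir / "vigilances.csv", index=False)
    dtime = time.time() - t0
    summary_out = {k: v for k, v in summary.items()
                   if k not in ("vigilances", "skipped_supervisors")}
    summary_out["n_region_cells"] = int(region_mask.sum())
    summary_out["n_out_region_cells"] = int((~region_mask).sum())
    summary_out["seconds"] = round(dtime, 2)
    (out_dir / "summary.json").write_text(json.dumps(summary_out, indent=1))
    log.info(
        "stage4: %d united place cells, mean rho %.4f, %.1f s",
        summary["n_united_place_cells"], summary["mean_rho"], dtime,
    )
    _update_manifest(out_dir, "stage4", summary_out)
    return cells, summary


def run_all(cfg: RunConfig, out_dir: str | Path) -> dict:
    """Run the four stages in order; returns the stage-4 summary."""
    run_stage1(cfg, out_dir)
    run_stage2(cfg, out_dir)
    run_stage3(cfg, out_dir)
    _, summary = run_stage4(cfg, out_dir)
    return summary
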