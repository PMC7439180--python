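"""Run configuration with canonical defaults and a reduced-scale fixture.

The defaults reproduce the full simulation conditions: an 80 x 60 m arena
explored at 2 m/s for 1e5 s, place fields 1-15 m wide within 20 m of a
wall, the delayed-Hebbian parameters (eta = 5e-6 per 0.1 s update, h = 5,
S = 7, bounds [0, 5]), the GA settings (N = 100, M = 10, pc = 0.6, pm = 0.1, Psi = 1,
K = 500 records/generation, 1e5 s budget per fit) and the ART settings
(alpha = 0.001, beta = 1, 0.5 m lattice, rho step 0.001).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, replace
from pathlib import Path

import yaml

__all__ = ["RunConfig", "default_config", "make_fixture", "load_config"]


@dataclass(frozen=True)
class RunConfig:
    # arena / exploration
    width: float = 80.0  # L1 (m)
    height: float = 60.0  # L2 (m)
    speed: float = 2.0  # v (m/s)
    dt: float = 1.0  # s, recruitment-check / GA sampling interval
    hebb_dt: float = 0.1  # s, simulation step for walk + weight updates
    duration: float = 1e5  # exploration time for stages 1-2 (s)
    turn_sigma: float = 0.2  # rad/sqrt(s), correlated-walk turning noise
    # visual place cells
    max_rate: float = 10.0  # A (Hz)
    l_min: float = 1.0  # m
    l_max: float = 15.0  # m
    d_max: float = 20.0  # D (m)
    field_const: float = 30.0  # L
    # delayed-Hebbian learning
    eta: float = 5e-6
    h: float = 5.0
    s_const: float = 7.0
    th_down: float = 0.0
    th_up: float = 5.0
    tau_list: tuple[int, ...] = (4, 5, 6, 7)
    # genetic algorithm
    ga_n_pop: int = 100  # N
    ga_m_bits: int = 10  # M
    ga_pc: float = 0.6
    ga_pm: float = 0.1
    ga_k_records: int = 500  # K
    ga_psi: float = 1.0  # Psi
    ga_budget: float = 1e5  # s per fit
    # supervised fuzzy ART
    art_alpha: float = 0.001
    art_beta: float = 1.0
    art_spacing: float = 0.5  # m, sample lattice
    art_rho_step: float = 0.001
    # bookkeeping
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        d["tau_list"] = list(self.tau_list)
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def with_(self, **kwargs) -> "RunConfig":
        return replace(self, **kwargs)


def default_config(seed: int = 0) -> RunConfig:
    return RunConfig(seed=seed)


def make_fixture(scale: float = 0.25, seed: int = 0) -> RunConfig:
    """Geometrically reduced configuration for fast runs.

    Lengths (arena sides, l_min, l_max, D, L) shrink linearly with
    ``scale``; durations, population size and record counts shrink faster
    (exponents chosen so runtime falls roughly quadratically).  scale = 1
    returns the canonical defaults; the default scale = 0.25 gives a
    20 x 15 m arena, 1e4 s exploration, N = 20 and K = 100 — a pipeline
    that completes in well under two minutes.
    """
    if not 0.0 < scale <= 1.0:
        raise ValueError("scale must lie in (0, 1]")
    if scale == 1.0:
        return default_config(seed)
    t_exp = math.log(10.0) / math.log(4.0)  # 1e5 -> 1e4 at scale 0.25
    n_exp = math.log(5.0) / math.log(4.0)  # 100 -> 20, 500 -> 100
    return RunConfig(
        width=80.0 * scale,
        height=60.0 * scale,
        duration=round(1e5 * scale**t_exp),
        l_min=1.0 * scale,
        l_max=15.0 * scale,
        d_max=20.0 * scale,
        field_const=max(1.5, 30.0 * scale),
        ga_n_pop=max(2, round(100 * scale**n_exp)),
        ga_k_records=max(10, round(500 * scale**n_exp)),
        ga_budget=round(1e5 * scale**t_exp),
        art_spacing=0.5 * scale,
        seed=seed,
    )


def load_config(path: str | Path, **overrides) -> RunConfig:
    """Load a YAML or JSON configuration; unspecified fields keep defaults."""
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if data is None:
        data = {}
    if "tau_list" in data:
        data["tau_list"] = tuple(int(t) for t in data["tau_list"])
    data.update(overrides)
    return RunConfig(**data)

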