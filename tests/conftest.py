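"""Shared fixtures: a tiny arena/place map for unit tests and one
reduced-scale pipeline run shared by the pipeline-level tests."""

from __future__ import annotations

import numpy as np
import pytest

from unitedcells import (
    Arena,
    make_fixture,
    random_walk,
    run_recruitment,
)
from unitedcells.pipeline import run_all


@pytest.fixture(scope="session")
def tiny_arena() -> Arena:
    return Arena(width=20.0, height=15.0, d_max=5.0, field_const=7.5)


@pytest.fixture(scope="session")
def tiny_pmap(tiny_arena):
    """A few hundred place cells recruited on a short walk."""
    walk = random_walk(tiny_arena, 2.0, 4000, 1.0, seed=11)
    return run_recruitment(walk, tiny_arena, l_min=0.5, l_max=3.75)


@pytest.fixture(scope="session")
def fixture_cfg():
    return make_fixture(scale=0.25, seed=3)


@pytest.fixture(scope="session")
def fixture_run(fixture_cfg, tmp_path_factory):
    """One full reduced-scale pipeline run (about a minute)."""
    out = tmp_path_factory.mktemp("fixture_run")
    summary = run_all(fixture_cfg, out)
    return fixture_cfg, out, summary
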