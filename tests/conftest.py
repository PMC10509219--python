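"""Shared fixtures and independent oracles."""

from __future__ import annotations

import numpy as np
import pytest

from aqequity import (
    CRF,
    SyntheticConfig,
    build_constraints,
    make_toy_fixture,
    make_world,
    scale_inventory,
    source_total_mortality,
)


@pytest.fixture(scope="session")
def toy():
    return make_toy_fixture()


@pytest.fixture(scope="session")
def small_world():
    """A compact synthetic world reused across read-only tests."""
    return make_world(SyntheticConfig(n_cells_x=10, n_cells_y=10, n_point_sources=30,
                                      n_area_sources=40, n_states=2, seed=42))


@pytest.fixture(scope="session")
def small_study(small_world):
    """Baseline + policy inventories with TM/CO2 vectors and constraints."""
    grid, pop, inv, srm, incidence, scaling = small_world
    inv_policy = scale_inventory(inv, scaling)
    tm = source_total_mortality(inv, srm, pop, incidence, CRF(form="linear"),
                                group="minority")
    co2 = np.array([s.co2 for s in inv])
    spec = build_constraints(inv, inv_policy, "nation-total", tm=tm)
    return {
        "grid": grid, "pop": pop, "inv": inv, "inv_policy": inv_policy,
        "srm": srm, "incidence": incidence, "scaling": scaling,
        "tm": tm, "co2": co2, "spec": spec,
    }


def enumerate_vertex_optimum(tm: np.ndarray, co2: np.ndarray, target: float,
                             sense: str = "min") -> float:
    """Brute-force LP optimum by enumerating basic feasible solutions.

    With one equality constraint over box-bounded variables, every vertex
    has at most one fractional coordinate: enumerate all binary subsets and
    all (subset, fractional j) completions hitting the target exactly.
    Independent of both the LP solver and the greedy oracle.
    """
    tm = np.asarray(tm, dtype=float)
    co2 = np.asarray(co2, dtype=float)
    n = len(tm)
    subsets = (np.arange(2 ** n)[:, None] >> np.arange(n)) & 1
    co2_sums = subsets @ co2
    obj_sums = subsets @ tm
    atol = 1e-9 * max(target, 1.0)
    cands = list(obj_sums[np.abs(co2_sums - target) <= atol])
    for j in range(n):
        free = subsets[:, j] == 0
        frac = (target - co2_sums[free]) / co2[j]
        ok = (frac > 0) & (frac < 1)
        cands.extend(obj_sums[free][ok] + frac[ok] * tm[j])
    if not cands:
        raise AssertionError("no feasible vertex found")
    return float(min(cands) if sense == "min" else max(cands))


def random_single_group_instance(rng: np.random.Generator, n_max: int = 12):
    """A feasible random single-constraint allocation instance."""
    n = int(rng.integers(2, n_max + 1))
    tm = rng.uniform(0.0, 10.0, size=n)
    co2 = rng.uniform(0.1, 5.0, size=n)
    target = float(rng.uniform(0.0, 1.0) * co2.sum())
    return tm, co2, target
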