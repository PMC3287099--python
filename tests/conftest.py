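"""Shared fixtures.

The expensive fixture is ``cohort_bank``: 20 independently seeded synthetic
cohorts of 8 tumors each on the default 6 mm / 100x100 grid, every tumor
solved to a stationary oxygenation map.  Its reference hypoxia masks use
the solver-matched diffusion distance so that area-based validation is
meaningful.  It is session-scoped and shared by the electrode, variance
and acceptance tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest

from oxymap import (
    GridGeometry,
    SynthParams,
    cohort_params,
    generate_cohort,
    solve_to_stationary_hypoxia,
)
from oxymap.solver import SolverParams, effective_diffusion_distance


@pytest.fixture(scope="session")
def geometry() -> GridGeometry:
    return GridGeometry()


@pytest.fixture(scope="session")
def solver_params() -> SolverParams:
    return SolverParams()


@pytest.fixture(scope="session")
def matched_limit_mm(solver_params, geometry) -> float:
    """Single-vessel HP5 diffusion distance implied by the solver defaults."""
    return effective_diffusion_distance(solver_params, geometry, threshold_pct=5.0)


@dataclass
class SolvedCohort:
    domains: list
    solves: list

    @property
    def fields(self):
        return [(d, r.K) for d, r in zip(self.domains, self.solves)]


@pytest.fixture(scope="session")
def cohort_bank(geometry, solver_params, matched_limit_mm) -> list[SolvedCohort]:
    """20 solved cohorts of 8 synthetic tumors with matched reference hypoxia."""
    base = SynthParams(diffusion_limit_mm=matched_limit_mm)
    bank = []
    for ci in range(20):
        params = cohort_params(8, seed=100 + ci, base=base)
        domains = generate_cohort(8, params, geometry)
        solves = [solve_to_stationary_hypoxia(d, solver_params) for d in domains]
        bank.append(SolvedCohort(domains, solves))
    return bank


@pytest.fixture(scope="session")
def solved_tumor(geometry, solver_params, matched_limit_mm):
    """One default synthetic tumor with its converged solve result."""
    from oxymap import generate_domain

    dom = generate_domain(SynthParams(diffusion_limit_mm=matched_limit_mm, seed=7), geometry)
    res = solve_to_stationary_hypoxia(dom, solver_params)
    return dom, res
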