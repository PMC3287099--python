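"""Solver correctness: conservation, closed forms, direct-solve oracle,
stationarity of relative hypoxic fractions."""

import numpy as np
import pytest

from oxymap import GridGeometry, SynthParams, generate_domain
from oxymap.hypoxia import hypoxic_area_fraction, hypoxic_mask
from oxymap.solver import (
    SolverParams,
    StabilityError,
    advance,
    effective_diffusion_distance,
    initialize,
    solve_to_stationary_hypoxia,
    stationary_oxygen,
    step,
)

GEOM = GridGeometry()


def _dx_dt(params, geometry=GEOM):
    return params.dx_cm(geometry), params.dt(geometry)


class TestScheme:
    def test_constant_field_is_fixed_point_without_reactions(self):
        params = SolverParams(r=0.0, phi=0.0, eta=0.0, rho=0.0, gamma=0.0)
        dx, dt = _dx_dt(params)
        K0 = np.full((40, 40), 3.7)
        c0 = np.full((40, 40), 1.0)
        K, c = advance(K0, c0, np.zeros((40, 40)), params, dx, dt, 25)
        assert np.array_equal(K, K0)

    def test_mass_conserved_without_sources_or_sinks(self):
        """No-flux five-point stencil conserves total oxygen to 1e-12
        relative per step."""
        params = SolverParams(r=0.0, phi=0.0, eta=0.0, rho=0.0, gamma=0.0)
        dx, dt = _dx_dt(params)
        rng = np.random.default_rng(0)
        K0 = rng.random((50, 50))
        n_steps = 50
        K, _c = advance(K0, np.zeros((50, 50)), np.zeros((50, 50)), params, dx, dt, n_steps)
        rel = abs(K.sum() - K0.sum()) / K0.sum()
        assert rel < n_steps * 1e-12

    def test_uniform_source_reaches_supply_consumption_balance(self):
        """With sources everywhere and frozen uniform cells the field
        converges to K = r / (phi * c) at every cell."""
        params = SolverParams(rho=0.0, gamma=0.0, D_c=0.0)
        dx, dt = _dx_dt(params)
        n = 30
        m_p = np.ones((n, n))
        c = np.full((n, n), params.c_lim)
        K, _ = advance(np.zeros((n, n)), c, m_p, params, dx, dt, 2000)
        expected = params.r / (params.phi * params.c_lim)
        assert np.allclose(K, expected, rtol=1e-6)

    def test_nonnegativity_preserved(self):
        for seed in range(3):
            dom = generate_domain(SynthParams(seed=seed), GEOM)
            params = SolverParams()
            state = initialize(dom, params)
            K, c = advance(state.K, state.c, dom.perfused_mask.astype(float),
                           params, params.dx_cm(GEOM), params.dt(GEOM), 300)
            assert (K >= 0).all() and (c >= 0).all()

    def test_blowup_raises_stability_error(self):
        """A consumption rate far beyond the explicit stability bound must
        be reported, not silently produce garbage."""
        dom = generate_domain(SynthParams(seed=0), GEOM)
        params = SolverParams(phi=1.0)  # dt*phi*c_lim >> 2
        state = initialize(dom, params)
        with pytest.raises(StabilityError), np.errstate(over="ignore", invalid="ignore"):
            for _ in range(400):
                state = step(state, dom, params)


class TestDirectSolveOracle:
    def test_1d_strip_profile_matches_sparse_solve(self):
        """Explicit stepping on an n x 1 strip with a single source agrees
        with the direct stationary linear solve to 1e-8 of the profile scale."""
        params = SolverParams(rho=0.0, gamma=0.0, D_c=0.0)
        n = 48
        m_p = np.zeros((n, 1))
        m_p[12, 0] = 1.0
        c = np.full((n, 1), params.c_lim)
        dx, dt = params.dx_cm(GEOM), params.dt(GEOM)
        K, _ = advance(np.zeros((n, 1)), c, m_p, params, dx, dt, 6000)
        K_direct = stationary_oxygen(m_p, params.eta + params.phi * c, params, dx)
        assert np.abs(K - K_direct).max() / K_direct.max() < 1e-8

    def test_2d_single_source_matches_sparse_solve(self):
        params = SolverParams(rho=0.0, gamma=0.0, D_c=0.0)
        n = 32
        m_p = np.zeros((n, n))
        m_p[16, 16] = 1.0
        c = np.full((n, n), params.c_lim)
        dx, dt = params.dx_cm(GEOM), params.dt(GEOM)
        K, _ = advance(np.zeros((n, n)), c, m_p, params, dx, dt, 6000)
        K_direct = stationary_oxygen(m_p, params.eta + params.phi * c, params, dx)
        assert np.abs(K - K_direct).max() / K_direct.max() < 1e-7


class TestInitialize:
    def test_oxygen_starts_only_in_perfused_vessels(self):
        dom = generate_domain(SynthParams(seed=1), GEOM)
        params = SolverParams(K_vessel=2.5)
        state = initialize(dom, params)
        assert np.allclose(state.K.sum(), 2.5 * dom.perfused_mask.sum())
        assert not state.K[~dom.perfused_mask].any()

    def test_no_perfusion_gives_zero_oxygen(self):
        dom = generate_domain(SynthParams(perfused_fraction=0.0, seed=1), GEOM)
        state = initialize(dom)
        assert not state.K.any()

    def test_gaussian_cells_peak_at_centroid(self):
        dom = generate_domain(SynthParams(seed=1), GEOM)
        params = SolverParams(c0_peak=123.0)
        state = initialize(dom, params)
        cx, cy = dom.tumor_centroid_mm()
        i, j = dom.geometry.cell_of(cx, cy)
        assert state.c[i, j] == pytest.approx(123.0, rel=1e-3)
        assert not state.c[~dom.tumor_mask].any()


class TestStationarity:
    def test_hp_stable_between_half_and_full_horizon(self, solved_tumor):
        dom, res = solved_tumor
        tr = res.trace
        T = tr["t"].iloc[-1]
        for col in ("HP2.5", "HP5", "HP10"):
            at_half = np.interp(T / 2, tr["t"], tr[col])
            assert abs(tr[col].iloc[-1] - at_half) < 0.005

    def test_fully_perfused_domain_has_no_hypoxia(self):
        n = 40
        g = GridGeometry(extent_mm=2.4, n=n)
        full = np.ones((n, n), bool)
        from oxymap.grid import VascularDomain

        dom = VascularDomain(g, full, full, full)
        res = solve_to_stationary_hypoxia(dom, SolverParams())
        assert hypoxic_area_fraction(res.K, dom.tumor_mask, 10.0) == 0.0

    def test_degenerate_domain_flagged_with_full_hypoxia(self):
        dom = generate_domain(SynthParams(perfused_fraction=0.0, seed=2), GEOM)
        with pytest.warns(UserWarning, match="no perfused vessel"):
            res = solve_to_stationary_hypoxia(dom, SolverParams())
        assert res.state.degenerate
        assert not res.converged
        assert res.trace["HP10"].iloc[-1] == 1.0

    def test_relative_hypoxia_invariant_to_oxygen_scale(self):
        """Scaling supply rate and vessel oxygen by a power of two leaves
        the hypoxic masks bit-identical (the relative definition at work)."""
        dom = generate_domain(SynthParams(seed=3), GEOM)
        p1 = SolverParams()
        p8 = SolverParams(r=p1.r * 8.0, K_vessel=p1.K_vessel * 8.0)
        r1 = solve_to_stationary_hypoxia(dom, p1)
        r8 = solve_to_stationary_hypoxia(dom, p8)
        for pct in (2.5, 5.0, 10.0):
            assert np.array_equal(
                hypoxic_mask(r1.K, dom.tumor_mask, pct),
                hypoxic_mask(r8.K, dom.tumor_mask, pct),
            )


class TestDiffusionDistance:
    def test_distance_orders_with_threshold(self):
        params = SolverParams()
        d25 = effective_diffusion_distance(params, GEOM, 2.5)
        d5 = effective_diffusion_distance(params, GEOM, 5.0)
        d10 = effective_diffusion_distance(params, GEOM, 10.0)
        assert d25 > d5 > d10 > 0.05
        assert d25 < 1.0  # well inside the 6 mm domain

    def test_lower_consumption_diffuses_farther(self):
        params = SolverParams()
        half = SolverParams(phi=params.phi / 4.0)
        assert (effective_diffusion_distance(half, GEOM, 5.0)
                > effective_diffusion_distance(params, GEOM, 5.0))
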