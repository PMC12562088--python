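"""Kernels, Douglas ADI stepping, field updates and CFL bounds."""

import math

import numpy as np
import pytest

from angioturing.params import default_parameters
from angioturing.pde_core import (CFLReport, DoseSchedule, FieldState, Grid2D,
                                  MissingParameterError, OutOfDomainError,
                                  adi_step, cfl_dt, deposit_kernels,
                                  domain_integral, step_drug, step_oxygen,
                                  step_taf)


# ---------------------------------------------------------------------------
# kernels

class TestDepositKernels:
    def test_empty_positions_give_zero_field(self, grid):
        assert np.all(deposit_kernels([], grid, Rc=0.05) == 0.0)

    def test_single_agent_discrete_integral_is_one(self, grid):
        field = deposit_kernels([np.array([0.5, 0.5])], grid, Rc=grid.dx / 2)
        assert field.sum() * grid.dx * grid.dy == pytest.approx(1.0, rel=1e-12)

    def test_subgrid_disk_falls_back_to_nearest_node(self, grid):
        field = deposit_kernels([np.array([0.52, 0.48])], grid, Rc=1e-4)
        assert np.count_nonzero(field) == 1
        assert field.sum() * grid.dx * grid.dy == pytest.approx(1.0, rel=1e-12)

    def test_coincident_agents_add_linearly(self, grid):
        one = deposit_kernels([np.array([0.4, 0.6])], grid, Rc=0.1)
        two = deposit_kernels([np.array([0.4, 0.6])] * 2, grid, Rc=0.1)
        np.testing.assert_allclose(two, 2.0 * one, rtol=1e-13)

    def test_weights_scale_each_agent(self, grid):
        w = deposit_kernels([np.array([0.5, 0.5])], grid, Rc=0.1, weights=[2.5])
        assert w.sum() * grid.dx * grid.dy == pytest.approx(2.5, rel=1e-12)

    def test_position_outside_domain_raises(self, grid):
        with pytest.raises(OutOfDomainError):
            deposit_kernels([np.array([1.5, 0.5])], grid, Rc=0.1)


# ---------------------------------------------------------------------------
# ADI scheme

class TestADI:
    def test_uniform_field_with_zero_reaction_is_invariant(self, grid):
        u = np.full(grid.shape, 3.7)
        out = adi_step(u, Dcoef=0.12, reaction=None, dt=0.1, grid=grid)
        np.testing.assert_allclose(out, u, rtol=1e-14)

    def test_exponential_decay_oracle_converges_with_dt(self, grid):
        """Uniform decay du/dt = -xi u has exact solution u0 exp(-xi t).
        With the reaction evaluated explicitly at the start-of-step state
        the reaction integration is forward Euler: the local truncation is
        O(dt^2), so the global error halves with dt (Richardson ratio 2)
        and is tiny in absolute terms."""
        xi, u0, T = 0.01, 2.0, 1.0
        exact = u0 * math.exp(-xi * T)
        errors = []
        for nsteps in (100, 200):
            dt = T / nsteps
            u = np.full(grid.shape, u0)
            for _ in range(nsteps):
                u = adi_step(u, 0.12, lambda v: -xi * v, dt, grid)
            errors.append(abs(u[3, 3] - exact))
        assert errors[0] / errors[1] == pytest.approx(2.0, rel=0.1)
        assert errors[0] < 1e-4 * exact

    def test_pure_diffusion_l2_norm_nonincreasing(self, grid, rng):
        u = rng.uniform(0.0, 1.0, grid.shape)
        norms = [np.linalg.norm(u)]
        for _ in range(20):
            u = adi_step(u, 0.5, None, dt=0.5, grid=grid)
            norms.append(np.linalg.norm(u))
        assert all(b <= a * (1 + 1e-12) for a, b in zip(norms, norms[1:]))

    def test_space_time_refinement_shrinks_error_fourfold(self):
        """O(dt^2 + h^2) consistency: halving both h and dt reduces the
        error against the exact cosine-mode decay solution by ~4x."""
        D, T = 0.12, 0.5
        errs = []
        for N, nsteps in ((11, 10), (21, 20)):
            g = Grid2D(N, N, 1.0, 1.0)
            x, y = g.node_coords()
            lam = 2 * math.pi ** 2
            u = np.cos(math.pi * x)[:, None] * np.cos(math.pi * y)[None, :]
            exact = u * math.exp(-D * lam * T)
            dt = T / nsteps
            for _ in range(nsteps):
                u = adi_step(u, D, None, dt, g)
            errs.append(np.max(np.abs(u - exact)))
        assert errs[0] / errs[1] == pytest.approx(4.0, rel=0.4)

    def test_periodic_uniform_invariance(self):
        g = Grid2D(16, 16, 1.0, 1.0, bc="periodic")
        u = np.full(g.shape, 1.3)
        np.testing.assert_allclose(adi_step(u, 0.3, None, 0.2, g), u, rtol=1e-13)

    def test_periodic_plane_wave_decay(self):
        """On a periodic grid the discrete Fourier mode decays at the exact
        rate of the ADI amplification factor, which tends to exp(-D lam t)."""
        g = Grid2D(64, 64, 1.0, 1.0, bc="periodic")
        x, y = g.node_coords()
        u = np.cos(2 * math.pi * x)[:, None] * np.ones(g.Ny)[None, :]
        lam = (2 * math.pi) ** 2
        D, dt, nsteps = 0.1, 0.005, 40
        for _ in range(nsteps):
            u = adi_step(u, D, None, dt, g)
        assert u.max() == pytest.approx(math.exp(-D * lam * dt * nsteps), rel=2e-2)

    def test_nonfinite_input_raises(self, grid):
        u = np.full(grid.shape, np.nan)
        with pytest.raises(FloatingPointError):
            adi_step(u, 0.1, None, 0.1, grid)

    def test_nonnegativity_preserved_for_smooth_fields(self, grid):
        """Nonnegative smooth concentration profiles stay nonnegative over
        CFL-compliant steps at the reference parameters.  (Positivity of
        the implicit scheme holds for resolved fields; rough white-noise
        data at diffusion numbers far above 1/2 are outside that envelope.)"""
        p = default_parameters()
        dt = cfl_dt(p, np.zeros(grid.shape), grid).dt
        x, y = grid.node_coords()
        for seed in range(100):
            rng = np.random.default_rng(seed)
            u = np.full(grid.shape, 0.5)
            for _ in range(3):  # a few random low-order cosine modes
                px, qy = rng.integers(0, 3, 2)
                amp = rng.uniform(-0.13, 0.13)
                u += amp * np.outer(np.cos(px * np.pi * x), np.cos(qy * np.pi * y))
            assert u.min() >= 0.0
            out = adi_step(u, p.Dc, lambda v: -p.xi_c * v, dt, grid)
            assert out.min() >= -1e-12


# ---------------------------------------------------------------------------
# field-specific steps

class TestFieldSteps:
    def test_taf_pure_decay_matches_exponential(self, grid):
        p = default_parameters()
        zero = np.zeros(grid.shape)
        state = FieldState.uniform(grid, c=1.0)
        dt = 0.01
        for _ in range(100):
            state.c = step_taf(state, zero, zero, p, dt)
        assert state.c[5, 5] == pytest.approx(math.exp(-p.xi_c * 1.0), rel=1e-4)

    def test_taf_source_mass_balance_single_hypoxic_cell(self, grid):
        """With uptake and decay off, each step adds exactly eta*dt of TAF
        mass (the renormalized kernel integrates to one)."""
        p = default_parameters().replace(xi_c=0.0, lam_uptake=0.0, eta=2.0)
        hyp = deposit_kernels([np.array([0.5, 0.5])], grid, p.Rc)
        state = FieldState.uniform(grid, c=0.0)
        dt = 0.01
        for step in range(5):
            state.c = step_taf(state, hyp, np.zeros(grid.shape), p, dt)
        # the trapezoid-quadrature mass is conserved exactly by the
        # mirror-closure ADI sweeps, so the balance is sharp
        assert domain_integral(state.c, grid) == pytest.approx(
            p.eta * dt * 5, rel=1e-10)

    def test_taf_rejects_negative_density(self, grid, uniform_state):
        p = default_parameters()
        bad = np.full(grid.shape, -0.1)
        with pytest.raises(ValueError):
            step_taf(uniform_state, bad, np.zeros(grid.shape), p, 0.01)

    def test_drug_vascular_source_silent_in_off_window(self, grid):
        p = default_parameters()
        sched = DoseSchedule(mode="pulsed", Sd_level=2.0, on_duration=1.0,
                             off_duration=1.0)
        ves = deposit_kernels([np.array([0.5, 0.5])], grid, p.Rc)
        zero = np.zeros(grid.shape)
        state = FieldState.uniform(grid, d=0.0)
        state.t = 1.5  # inside the off window
        out = step_drug(state, zero, ves, sched, p, 0.01)
        assert np.all(out == 0.0)
        state.t = 0.5  # inside the on window
        out = step_drug(state, zero, ves, sched, p, 0.01)
        assert out.sum() > 0.0

    def test_drug_decay_without_cells(self, grid):
        p = default_parameters()
        sched = DoseSchedule(mode="pulsed", Sd_level=2.0, on_duration=1.0,
                             off_duration=1.0, t_start=10.0)
        zero = np.zeros(grid.shape)
        state = FieldState.uniform(grid, d=0.4)
        for _ in range(50):
            state.d = step_drug(state, zero, zero, sched, p, 0.02)
        assert state.d[2, 2] == pytest.approx(0.4 * math.exp(-p.xi_d * 1.0), rel=1e-4)

    def test_mm_uptake_reduces_to_linear_at_low_concentration(self, grid):
        p = default_parameters().replace(Kd=1.0, xi_d=0.0)
        d0 = p.Kd / 100
        tum = deposit_kernels([np.array([0.5, 0.5])], grid, p.Rc)
        zero = np.zeros(grid.shape)
        sched = DoseSchedule(mode="pulsed", Sd_level=0.0, on_duration=1, off_duration=1)
        lin_p = p.replace(rho_d=p.rho_d / p.Kd)
        s1 = FieldState.uniform(grid, d=d0)
        s2 = FieldState.uniform(grid, d=d0)
        mm = step_drug(s1, tum, zero, sched, p, 1e-3, kinetics="michaelis_menten")
        lin = step_drug(s2, tum, zero, sched, lin_p, 1e-3, kinetics="linear")
        up_mm = d0 - mm.min()
        up_lin = d0 - lin.min()
        assert up_mm == pytest.approx(up_lin, rel=0.02)

    def test_mm_without_half_saturation_raises(self, grid, uniform_state):
        p = default_parameters()  # Kd is None
        zero = np.zeros(grid.shape)
        sched = DoseSchedule()
        with pytest.raises(MissingParameterError):
            step_drug(uniform_state, zero, zero, sched, p, 0.01,
                      kinetics="michaelis_menten")
        with pytest.raises(MissingParameterError):
            step_oxygen(uniform_state, zero, zero, p, 0.01,
                        kinetics="michaelis_menten")

    def test_oxygen_source_vanishes_at_saturation(self, grid):
        p = default_parameters()
        ves = np.full(grid.shape, 1.0)
        zero = np.zeros(grid.shape)
        state = FieldState.uniform(grid, o=1.0)
        out = step_oxygen(state, zero, ves, p, 0.01)
        # with o == 1 the vascular source is zero and only decay acts
        assert out.max() < 1.0

    def test_oxygen_relaxes_to_reaction_fixed_point(self, grid):
        """Uniform vessel density v: o* = So v / (xi_o + So v)."""
        p = default_parameters()
        v = 1.0
        ves = np.full(grid.shape, v)
        zero = np.zeros(grid.shape)
        state = FieldState.uniform(grid, o=0.3)
        target = p.So * v / (p.xi_o + p.So * v)
        for _ in range(400):
            state.o = step_oxygen(state, zero, ves, p, 0.05)
        assert abs(state.o[4, 9] - target) < 1e-6


# ---------------------------------------------------------------------------
# CFL

class TestCFL:
    def test_uniform_taf_gives_pure_diffusive_bound(self, grid):
        p = default_parameters()
        rep = cfl_dt(p, np.full(grid.shape, 0.3), grid)
        assert rep.dt == pytest.approx(grid.dx ** 2 / (4 * p.Dn), rel=1e-12)
        assert rep.mesh_ok

    def test_direct_evaluation_with_reference_diffusivity(self):
        g = Grid2D(101, 101, 5.0, 5.0)
        p = default_parameters()
        rep = cfl_dt(p, np.zeros(g.shape), g)
        assert g.dx == pytest.approx(0.05)
        assert rep.dt == pytest.approx(0.05 ** 2 / (4 * 4.61e-4), rel=1e-3)

    def test_returned_dt_never_exceeds_any_bound(self, grid, rng):
        p = default_parameters()
        for _ in range(10):
            c = rng.uniform(0, 5, grid.shape)
            rep = cfl_dt(p, c, grid)
            assert rep.dt <= rep.bound_diffusive * (1 + 1e-12)
            assert rep.dt <= rep.bound_gradient * (1 + 1e-12)
            assert rep.dt <= rep.bound_combined * (1 + 1e-12)

    def test_steep_gradient_flags_mesh_violation(self, grid):
        p = default_parameters()
        x, _ = grid.node_coords()
        c = np.outer(50.0 * x, np.ones(grid.Ny))
        rep = cfl_dt(p, c, grid)
        assert not rep.mesh_ok


class TestDoseSchedule:
    def test_continuous_rate_constant(self):
        s = DoseSchedule(mode="continuous", Sd_level=2.0)
        assert s.rate(0.0) == s.rate(17.3) == 2.0

    def test_pulsed_windows(self):
        s = DoseSchedule(mode="pulsed", Sd_level=1.5, on_duration=2.0,
                         off_duration=3.0, t_start=1.0)
        assert s.rate(0.5) == 0.0       # before treatment starts
        assert s.rate(1.5) == 1.5       # on-window
        assert s.rate(4.0) == 0.0       # off-window
        assert s.rate(6.5) == 1.5       # second cycle

    def test_pulsed_requires_positive_durations(self):
        with pytest.raises(ValueError):
            DoseSchedule(mode="pulsed", on_duration=0.0, off_duration=1.0)
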