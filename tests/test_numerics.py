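"""Tests of the spatial operators, stability bound and time integration."""

import dataclasses

import numpy as np
import pytest

import innatesim as im
from innatesim import _kernels
from conftest import oracle_rates


def minimal_params(**overrides):
    """A parameter set with every rate zero (capacities kept positive)."""
    base = {f.name: 0.0 for f in dataclasses.fields(im.ParameterSet)}
    base.update(keq_ch=1.0, keq_g=1.0, ch_inf=1.0, g_inf=1.0, ac_inf=1.0)
    base.update(overrides)
    return im.ParameterSet(**base)


class TestLaplacian:
    def test_constant_field_in_kernel(self):
        assert np.allclose(im.laplacian_neumann(np.full(7, 3.2), 0.1), 0.0)

    def test_three_node_example(self):
        np.testing.assert_allclose(
            im.laplacian_neumann(np.array([0.0, 1.0, 2.0]), 1.0), [2.0, 0.0, -2.0]
        )

    def test_conserves_trapezoid_mass(self):
        rng = np.random.default_rng(3)
        f = rng.uniform(0, 10, size=41)
        out = im.laplacian_neumann(f, 0.125)
        assert abs(np.trapezoid(out)) < 1e-10 * np.abs(out).sum()

    def test_short_field_rejected(self):
        with pytest.raises(ValueError):
            im.laplacian_neumann(np.array([1.0, 2.0]), 0.1)


class TestChemotaxisUpwind:
    def test_uniform_chemoattractant(self):
        out = im.chemotaxis_divergence_upwind(
            np.array([1.0, 5.0, 2.0]), np.full(3, 4.0), 1.0, 0.5
        )
        assert np.all(out == 0.0)

    def test_three_node_fluxes(self):
        # rising chemoattractant: both interface fluxes equal chi*u_upwind*grad = 1;
        # the divergence drains the left node and fills the right one when
        # subtracted from the balance (boundary nodes own half-width cells).
        div = im.chemotaxis_divergence_upwind(
            np.ones(3), np.array([0.0, 1.0, 2.0]), 1.0, 1.0
        )
        np.testing.assert_allclose(div, [2.0, 0.0, -2.0])

    def test_cells_climb_the_gradient(self):
        cells = np.array([1.0, 1.0, 1.0, 1.0])
        chemo = np.array([0.0, 1.0, 2.0, 3.0])
        new = cells - 0.01 * im.chemotaxis_divergence_upwind(cells, chemo, 1.0, 1.0)
        assert new[-1] > cells[-1] and new[0] < cells[0]
        assert np.trapezoid(new) == pytest.approx(np.trapezoid(cells))

    def test_conserves_trapezoid_mass(self):
        rng = np.random.default_rng(4)
        u = rng.uniform(0, 5, 31)
        c = rng.uniform(0, 3, 31)
        out = im.chemotaxis_divergence_upwind(u, c, 0.7, 0.2)
        assert abs(np.trapezoid(out)) < 1e-12 * max(np.abs(out).sum(), 1.0)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            im.chemotaxis_divergence_upwind(np.ones(4), np.ones(5), 1.0, 0.1)


class TestStabilityBound:
    def test_unconstrained_is_infinite(self):
        assert im.stability_bound(minimal_params(), 0.1) == np.inf

    def test_single_diffusive_constraint(self):
        p = minimal_params(D_N=0.012096)
        assert im.stability_bound(p, 0.1) == pytest.approx(0.01 / 0.024192)

    def test_dx_scaling(self, params):
        # strictly dx^2 in the transport-limited regime ...
        p = minimal_params(D_N=0.012096, chi_N=0.0144, ch_inf=3.6)
        diff_bounds = [im.stability_bound(p, dx) for dx in (0.4, 0.2, 0.1, 0.05)]
        assert all(b1 > b2 for b1, b2 in zip(diff_bounds, diff_bounds[1:]))
        np.testing.assert_allclose(diff_bounds[0] / diff_bounds[1], 4.0)
        # ... and never increasing as dx shrinks once reactions dominate
        bounds = [im.stability_bound(params, dx) for dx in (0.4, 0.2, 0.1, 0.05)]
        assert all(b1 >= b2 for b1, b2 in zip(bounds, bounds[1:]))

    def test_step_above_bound_refused(self, params, grid51):
        bound = im.stability_bound(params, grid51.dx)
        s = im.initial_state(grid51)
        with pytest.raises(im.StabilityError, match="constraint"):
            im.euler_step(s, params, im.ScenarioFlags.from_case(5), 2 * bound)


class TestEulerStep:
    def test_pure_decay(self):
        """Single uncoupled species: one step of explicit-Euler decay."""
        p = minimal_params(mu_LPS=0.7)
        grid = im.Grid(length=1.0, nx=5)
        s = im.TissueState.zeros(grid)
        s.species("lps")[:] = 10.0
        dt = 1e-3
        out = im.euler_step(s, p, im.ScenarioFlags.from_case(5), dt)
        np.testing.assert_allclose(out.species("lps"), 10.0 * (1 - 0.7 * dt), rtol=1e-14)
        assert out.time == pytest.approx(dt)

    def test_neutrophil_bookkeeping(self, params, grid51):
        """Total N + ND changes only through influx and efferocytosis.

        Transport conserves the trapezoid mass and the N -> ND conversion
        cancels, so over one step the combined pool moves exactly by
        dt * (integrated influx - integrated efferocytosis).
        """
        rng = np.random.default_rng(5)
        dx = grid51.dx
        s = im.TissueState(grid51, 0.0, rng.uniform(0.1, 2.0, (8, grid51.nx)))
        f = im.ScenarioFlags.from_case(5)
        dt = 1e-5
        out = im.euler_step(s, params, f, dt)
        d_tot = (im.spatial_total(out.species("n"), dx)
                 + im.spatial_total(out.species("nd"), dx)
                 - im.spatial_total(s.species("n"), dx)
                 - im.spatial_total(s.species("nd"), dx))
        src = im.spatial_total(
            im.neutrophil_source(s.species("ch"), s.species("n"), params), dx
        )
        effero = im.spatial_total(
            params.lambda_ND_AM * s.species("nd") * s.species("am"), dx
        )
        assert d_tot == pytest.approx(dt * (src - effero), rel=1e-9)

    def test_disabled_species_untouched(self, params, grid51):
        rng = np.random.default_rng(6)
        s = im.TissueState(grid51, 0.0, rng.uniform(0.0, 1.0, (8, grid51.nx)))
        out = im.euler_step(s, params, im.ScenarioFlags.from_case(1), 1e-5)
        for name in ("ch", "n", "nd", "g", "ac"):
            np.testing.assert_array_equal(out.species(name), s.species(name))

    @pytest.mark.parametrize("case", [1, 2, 3, 4, 5])
    def test_kernel_matches_reference_path(self, params, case):
        """The compiled stepping kernel reproduces the numpy euler_step."""
        grid = im.Grid.from_spacing(5.0, 0.5)
        f = im.ScenarioFlags.from_case(case)
        ref = im.initial_state(grid)
        S = ref.fields.copy()
        R = np.empty_like(S)
        clamp = np.zeros(8, np.int64)
        dt = 1e-4
        nsteps = 50
        bad = _kernels.run_steps(S, R, nsteps, dt, grid.dx, params.as_array(),
                                 f.active, clamp)
        assert bad == (-1, -1)
        for _ in range(nsteps):
            ref = im.euler_step(ref, params, f, dt)
        np.testing.assert_allclose(S, ref.fields, rtol=1e-12, atol=1e-14)


class TestSimulate:
    def test_zero_horizon(self, params, grid51):
        traj = im.simulate(params, im.ScenarioFlags.from_case(5), grid51,
                           1e-5, 0.0, [0.0])
        assert len(traj.states) == 1
        np.testing.assert_array_equal(
            traj.states[0].fields, im.initial_state(grid51).fields
        )

    def test_deterministic(self, params, grid51):
        f = im.ScenarioFlags.from_case(5)
        a = im.simulate(params, f, grid51, 1e-5, 0.02, [0.01, 0.02])
        b = im.simulate(params, f, grid51, 1e-5, 0.02, [0.01, 0.02])
        for sa, sb in zip(a.states, b.states):
            np.testing.assert_array_equal(sa.fields, sb.fields)

    def test_mirror_symmetry(self, params, grid51):
        """Mirroring the initial condition mirrors the whole solution."""
        f = im.ScenarioFlags.from_case(5)
        left = im.initial_state(grid51)
        right = im.TissueState(grid51, 0.0, left.fields[:, ::-1].copy())
        a = im.simulate(params, f, grid51, 1e-5, 0.05, [0.05], initial=left)
        b = im.simulate(params, f, grid51, 1e-5, 0.05, [0.05], initial=right)
        np.testing.assert_allclose(
            a.states[-1].fields, b.states[-1].fields[:, ::-1], rtol=1e-10, atol=1e-12
        )

    @pytest.mark.parametrize("case", [1, 3, 5])
    def test_nonnegative_and_finite(self, params, grid51, case):
        rng = np.random.default_rng(10 + case)
        init = im.TissueState(
            grid51, 0.0,
            rng.uniform(0, 1, (8, grid51.nx)) * np.array([100, 2, 2, 3, 5, 5, 3, 3])[:, None],
        )
        traj = im.simulate(params, im.ScenarioFlags.from_case(case), grid51,
                           1e-5, 0.1, [0.05, 0.1], initial=init)
        for s in traj.states:
            assert np.all(np.isfinite(s.fields))
            assert np.all(s.fields >= 0)

    def test_uniform_diffusion_free_matches_0d_integration(self, param_dict):
        """Without transport, every node follows the 0-D kinetics."""
        q = dict(param_dict)
        for name in ("D_LPS", "D_RM", "D_AM", "D_CH", "D_N", "D_ND", "D_G", "D_AC",
                     "chi_RM", "chi_AM", "chi_N"):
            q[name] = 0.0
        p = im.ParameterSet(**q)
        grid = im.Grid(length=1.0, nx=5)
        init = im.TissueState.zeros(grid)
        init.species("lps")[:] = 10.0
        init.species("rm")[:] = 1.0
        dt, t_final = 1e-5, 0.1
        traj = im.simulate(p, im.ScenarioFlags.from_case(5), grid, dt, t_final,
                           [t_final], initial=init)
        # independently coded scalar Euler integration of the naive kinetics
        y = [10.0, 1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 0.0]
        for _ in range(int(round(t_final / dt))):
            r = oracle_rates(y, q, 5)
            y = [max(v + dt * rv, 0.0) for v, rv in zip(y, r)]
        final = traj.states[-1].fields
        for k, want in enumerate(y):
            np.testing.assert_allclose(final[k], want, rtol=1e-8, atol=1e-12)

    def test_bad_output_times_rejected(self, params, grid51):
        f = im.ScenarioFlags.from_case(5)
        with pytest.raises(ValueError):
            im.simulate(params, f, grid51, 1e-5, 1.0, [0.5, 0.5])
        with pytest.raises(ValueError):
            im.simulate(params, f, grid51, 1e-5, 1.0, [0.5, 2.0])
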