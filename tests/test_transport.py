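"""Forward-model operators: upwind advection, diffusion, chemistry,
deposition, emission injection, and the operator-split integration."""

import numpy as np
import pytest

from pmadjoint import (ChemistryParams, ForwardModel, GridSpec, MetFields,
                       SpeciesSet, advect, chemistry_step, deposit, diffuse,
                       inject_emissions)
from pmadjoint.grid import ConfigurationError


def _grid(nx=8, ny=6, boundary="periodic", dt_s=3600.0):
    return GridSpec(nx=nx, ny=ny, dx_km=100.0, dt_s=dt_s, n_hours=4,
                    boundary=boundary)


def _stream_winds(grid, rng, speed=5.0):
    """Divergence-free (central-difference) cell-center winds."""
    psi = rng.standard_normal((grid.ny, grid.nx))
    u = -(np.roll(psi, -1, axis=0) - np.roll(psi, 1, axis=0)) / 2.0
    v = (np.roll(psi, -1, axis=1) - np.roll(psi, 1, axis=1)) / 2.0
    mx = np.abs(u).max() + np.abs(v).max()
    return u / mx * speed, v / mx * speed


class TestAdvection:
    def test_uniform_field_unchanged_divergence_free_wind(self):
        grid = _grid()
        rng = np.random.default_rng(0)
        u, v = _stream_winds(grid, rng, speed=10.0)
        field = np.full((grid.ny, grid.nx), 3.7)
        out = advect(field, u, v, grid)
        np.testing.assert_allclose(out, field, rtol=1e-13)

    def test_pulse_shifts_one_cell_east_at_unit_courant(self):
        grid = _grid()
        speed = grid.dx_m / grid.dt_s  # Courant number exactly 1
        u = np.full((grid.ny, grid.nx), speed)
        v = np.zeros_like(u)
        field = np.zeros((grid.ny, grid.nx))
        field[2, 3] = 1.0
        out = advect(field, u, v, grid)
        expected = np.zeros_like(field)
        expected[2, 4] = 1.0
        np.testing.assert_allclose(out, expected, atol=1e-14)

    def test_mass_conserved_periodic_any_wind(self):
        grid = _grid()
        rng = np.random.default_rng(1)
        # deliberately divergent winds: flux form must still conserve mass
        u = rng.uniform(-8, 8, (grid.ny, grid.nx))
        v = rng.uniform(-8, 8, (grid.ny, grid.nx))
        u *= 0.45 * grid.dx_m / grid.dt_s / np.abs(u).max()
        v *= 0.45 * grid.dx_m / grid.dt_s / np.abs(v).max()
        field = rng.uniform(0, 10, (grid.ny, grid.nx))
        out = advect(field, u, v, grid)
        assert abs(out.sum() - field.sum()) <= 1e-12 * field.sum()

    def test_zero_inflow_mass_non_increasing(self):
        grid = _grid(boundary="zero_inflow")
        rng = np.random.default_rng(2)
        u = np.full((grid.ny, grid.nx), 12.0)
        v = np.zeros_like(u)
        field = rng.uniform(0, 10, (grid.ny, grid.nx))
        before = field.sum()
        for _ in range(5):
            field = advect(field, u, v, grid)
        assert field.sum() < before
        assert (field >= -1e-15).all()

    def test_cfl_violation_names_inputs(self):
        grid = _grid()
        u = np.full((grid.ny, grid.nx), 50.0)  # 50 m/s, dt/dx = 0.036 -> 1.8
        with pytest.raises(ConfigurationError, match=r"max\|u\|.*dt=3600"):
            advect(np.ones((grid.ny, grid.nx)), u, np.zeros_like(u), grid)


class TestDiffusion:
    def test_zero_diffusivity_is_identity(self):
        grid = _grid()
        field = np.random.default_rng(0).uniform(0, 5, (grid.ny, grid.nx))
        np.testing.assert_array_equal(diffuse(field, 0.0, grid), field)

    def test_uniform_field_unchanged(self):
        grid = _grid()
        field = np.full((grid.ny, grid.nx), 2.5)
        np.testing.assert_allclose(diffuse(field, 400.0, grid), field, rtol=1e-13)

    def test_pulse_stencil_by_hand(self):
        grid = _grid()
        k = 500.0
        nu = k * grid.dt_s / grid.dx_m**2
        field = np.zeros((grid.ny, grid.nx))
        field[3, 4] = 1.0
        out = diffuse(field, k, grid)
        assert out[3, 4] == pytest.approx(1.0 - 4 * nu, rel=1e-13)
        for (j, i) in [(2, 4), (4, 4), (3, 3), (3, 5)]:
            assert out[j, i] == pytest.approx(nu, rel=1e-13)

    def test_mass_conserved_and_spread_reduced(self):
        grid = _grid()
        rng = np.random.default_rng(3)
        field = rng.uniform(0, 10, (grid.ny, grid.nx))
        out = diffuse(field, 600.0, grid)
        assert out.sum() == pytest.approx(field.sum(), rel=1e-13)
        assert out.max() - out.min() < field.max() - field.min()

    def test_stability_violation_rejected(self):
        grid = _grid()
        with pytest.raises(ConfigurationError, match="1/4"):
            diffuse(np.ones((grid.ny, grid.nx)), 1e6, grid)


class TestChemistry:
    def _conc(self, species, grid, value=10.0):
        c = np.zeros((species.n_species, grid.ny, grid.nx))
        for g in species.gases:
            c[species.index(g)] = value
        return c

    def test_zero_rates_identity(self, species):
        grid = _grid()
        zero = SpeciesSet(conversions=tuple(
            type(c)(c.gas, c.particle, 0.0, c.yield_fraction)
            for c in species.conversions))
        met = MetFields(np.zeros((4, grid.ny, grid.nx)),
                        np.zeros((4, grid.ny, grid.nx)),
                        np.ones((4, len(zero.conversions))))
        c = self._conc(zero, grid)
        out, _ = chemistry_step(c, zero, met, 0, 1.0)
        np.testing.assert_array_equal(out, c)

    def test_linear_first_order_amounts(self, species):
        grid = _grid()
        met = MetFields(np.zeros((4, grid.ny, grid.nx)),
                        np.zeros((4, grid.ny, grid.nx)),
                        np.ones((4, len(species.conversions))))
        c = self._conc(species, grid, value=8.0)
        out, _ = chemistry_step(c, species, met, 0, 1.0)
        for conv in species.conversions:
            gi, pi = species.index(conv.gas), species.index(conv.particle)
            np.testing.assert_allclose(out[gi], 8.0 * (1 - conv.rate_per_h),
                                       rtol=1e-13)
            np.testing.assert_allclose(
                out[pi], conv.yield_fraction * 8.0 * conv.rate_per_h, rtol=1e-13)

    def test_titration_regime_shuts_off_production(self, species):
        """Where gamma*NOx > O3bg: no particulate nitrate is produced, and the
        finite-difference slope of production w.r.t. NOx is non-positive."""
        grid = _grid(nx=1, ny=1)
        params = ChemistryParams("titration", titration_k=0.01,
                                 titration_gamma=1.0)
        o3 = np.full((4, 1, 1), 30.0)
        met = MetFields(np.zeros((4, 1, 1)), np.zeros((4, 1, 1)),
                        np.ones((4, len(species.conversions))), o3)
        ni, pi = species.index("NOX"), species.index("PNO3")

        def pno3_production(nox_value):
            c = np.zeros((species.n_species, 1, 1))
            c[ni] = nox_value
            out, _ = chemistry_step(c, species, met, 0, 1.0, params)
            return float(out[pi, 0, 0])

        assert pno3_production(50.0) == 0.0  # titrated: gamma*NOx > O3bg
        for base in (20.0, 40.0, 60.0):  # includes the negative-slope branch
            d = 1e-4
            slope = (pno3_production(base + d) - pno3_production(base - d)) / (2 * d)
            if base * params.titration_gamma > 30.0:
                assert slope <= 0.0
        # below half the titration point the slope is positive
        d = 1e-4
        assert (pno3_production(10.0 + d) - pno3_production(10.0 - d)) > 0

    def test_negative_concentrations_rejected(self, species):
        grid = _grid()
        met = MetFields(np.zeros((4, grid.ny, grid.nx)),
                        np.zeros((4, grid.ny, grid.nx)),
                        np.ones((4, len(species.conversions))))
        c = self._conc(species, grid)
        c[0, 0, 0] = -1.0
        with pytest.raises(ValueError, match="negative"):
            chemistry_step(c, species, met, 0, 1.0)


class TestDeposition:
    def test_zero_rate_identity(self):
        c = np.random.default_rng(0).uniform(0, 5, (3, 4, 4))
        np.testing.assert_array_equal(deposit(c, np.zeros(3), 1.0), c)

    def test_exact_exponential(self):
        c = np.full((2, 3, 3), 10.0)
        rates = np.array([0.1, 0.5])
        out = deposit(c, rates, 2.0)
        np.testing.assert_allclose(out[0], 10 * np.exp(-0.2), rtol=1e-14)
        np.testing.assert_allclose(out[1], 10 * np.exp(-1.0), rtol=1e-14)

    def test_semigroup_two_steps_equal_one_double_step(self):
        c = np.random.default_rng(1).uniform(0, 5, (3, 4, 4))
        rates = np.array([0.1, 0.3, 0.7])
        two = deposit(deposit(c, rates, 1.0), rates, 1.0)
        one = deposit(c, rates, 2.0)
        np.testing.assert_allclose(two, one, rtol=1e-14)


class TestInjection:
    def test_zero_emissions_identity(self):
        grid = _grid()
        c = np.ones((2, grid.ny, grid.nx))
        out = inject_emissions(c, np.zeros_like(c), grid, 1.0)
        np.testing.assert_array_equal(out, c)

    def test_unit_arithmetic(self):
        # 1 ton/hr into a 100 km x 100 km cell, 1000 m mixing height, 1 hour
        grid = GridSpec(1, 1, dx_km=100.0, dt_s=3600.0, n_hours=1,
                        mixing_height_m=1000.0)
        c = np.zeros((1, 1, 1))
        e = np.ones((1, 1, 1))
        out = inject_emissions(c, e, grid, 1.0)
        assert out[0, 0, 0] == pytest.approx(0.1, rel=1e-13)

    def test_linearity_in_emissions(self):
        grid = _grid()
        e = np.random.default_rng(2).uniform(0, 3, (2, grid.ny, grid.nx))
        c = np.zeros((2, grid.ny, grid.nx))
        one = inject_emissions(c, e, grid, 1.0)
        two = inject_emissions(c, 2 * e, grid, 1.0)
        np.testing.assert_allclose(two, 2 * one, rtol=1e-14)


class TestRunForward:
    def test_zero_emissions_zero_trajectory(self, species, small_grid, calm_met):
        model = ForwardModel(small_grid, species, calm_met)
        emis = np.zeros((species.n_species, small_grid.n_hours,
                         small_grid.ny, small_grid.nx))
        traj = model.run(emis)
        assert np.all(traj.concentrations == 0)

    def test_box_approaches_continuous_closed_form_as_dt_shrinks(self, species):
        """1x1 box, constant source, exponential loss: the discrete solution
        converges to r(1-e^{-kt})/k as the sub-step shrinks."""
        k = species.deposition_per_h["EC"]
        ei = species.index("EC")
        n_hours = 24
        errors = []
        for spr in (1, 2, 4):
            grid = GridSpec(1, 1, dx_km=100.0, dt_s=3600.0 / spr,
                            n_hours=n_hours, mixing_height_m=1000.0)
            met = MetFields(np.zeros((n_hours, 1, 1)), np.zeros((n_hours, 1, 1)),
                            np.ones((n_hours, len(species.conversions))))
            model = ForwardModel(grid, species, met)
            emis = np.zeros((species.n_species, n_hours, 1, 1))
            emis[ei] = 2.0
            traj = model.run(emis)
            r = 2.0 * 1e12 / grid.cell_volume_m3  # μg/m³ per hour
            exact = r * (1 - np.exp(-k * n_hours)) / k
            errors.append(abs(traj.concentrations[-1, ei, 0, 0] - exact) / exact)
        assert errors[0] < 0.05
        assert errors[1] < 0.6 * errors[0]
        assert errors[2] < 0.6 * errors[1]

    def test_periodic_no_loss_conserves_emitted_mass(self, species, small_grid):
        """No deposition/chemistry, periodic boundary: domain mass equals the
        total emitted mass to round-off."""
        lossless = SpeciesSet(
            deposition_per_h={s: 0.0 for s in species.names},
            conversions=tuple(type(c)(c.gas, c.particle, 0.0)
                              for c in species.conversions))
        rng = np.random.default_rng(4)
        nh = small_grid.n_hours
        psi = rng.standard_normal((small_grid.ny, small_grid.nx))
        u = -(np.roll(psi, -1, 0) - np.roll(psi, 1, 0)) / 2
        v = (np.roll(psi, -1, 1) - np.roll(psi, 1, 1)) / 2
        scale = 8.0 / (np.abs(u).max() + np.abs(v).max())
        met = MetFields(np.tile(u * scale, (nh, 1, 1)),
                        np.tile(v * scale, (nh, 1, 1)),
                        np.ones((nh, len(lossless.conversions))))
        model = ForwardModel(small_grid, lossless, met, diffusivity_m2s=300.0)
        emis = rng.uniform(0, 2, (lossless.n_species, nh,
                                  small_grid.ny, small_grid.nx))
        traj = model.run(emis)
        emitted_ug = emis.sum() * 1e12  # tons -> μg, 1 h each
        domain_ug = traj.concentrations[-1].sum() * small_grid.cell_volume_m3
        assert domain_ug == pytest.approx(emitted_ug, rel=1e-10)

    def test_trajectory_linear_in_emissions(self, species, small_grid, calm_met):
        model = ForwardModel(small_grid, species, calm_met, diffusivity_m2s=200.0)
        rng = np.random.default_rng(5)
        shape = (species.n_species, small_grid.n_hours,
                 small_grid.ny, small_grid.nx)
        e1, e2 = rng.uniform(0, 2, shape), rng.uniform(0, 2, shape)
        t1 = model.run(e1).concentrations
        t2 = model.run(e2).concentrations
        t12 = model.run(2.0 * e1 + 0.5 * e2).concentrations
        np.testing.assert_allclose(t12, 2.0 * t1 + 0.5 * t2, rtol=1e-10,
                                   atol=1e-12 * t1.max())

    def test_non_negativity(self, species, small_grid):
        rng = np.random.default_rng(6)
        nh = small_grid.n_hours
        u = np.full((nh, small_grid.ny, small_grid.nx), 6.0)
        v = np.full_like(u, -4.0)
        met = MetFields(u, v, np.ones((nh, len(species.conversions))))
        model = ForwardModel(small_grid, species, met, diffusivity_m2s=400.0)
        emis = rng.uniform(0, 3, (species.n_species, nh,
                                  small_grid.ny, small_grid.nx))
        traj = model.run(emis)
        assert (traj.concentrations >= 0).all()
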