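"""Discrete-adjoint correctness: duality, closed-form box sensitivities,
upwind causality, and the full-trajectory gradient identity."""

import numpy as np
import pytest

from pmadjoint import (ChemistryParams, ForwardModel, GemmCost, GridSpec,
                       LinearCost, MetFields, SpeciesSet,
                       emission_weighted_primary_pm, hourly_forcing,
                       run_adjoint)
from pmadjoint.adjoint import SensitivityField


def _model(nx=6, ny=5, n_hours=8, wind=(5.0, -3.0), diff=300.0, seed=0,
           mode="linear"):
    grid = GridSpec(nx, ny, dx_km=100.0, dt_s=3600.0, n_hours=n_hours)
    species = SpeciesSet()
    rng = np.random.default_rng(seed)
    u = np.full((n_hours, ny, nx), wind[0]) + rng.uniform(-1, 1, (n_hours, ny, nx))
    v = np.full((n_hours, ny, nx), wind[1]) + rng.uniform(-1, 1, (n_hours, ny, nx))
    temp = 1.0 + 0.3 * rng.random((n_hours, len(species.conversions)))
    o3 = rng.uniform(30, 60, (n_hours, ny, nx)) if mode == "titration" else None
    met = MetFields(u, v, temp, o3)
    chem = ChemistryParams(mode)
    return ForwardModel(grid, species, met, diff, chem)


class TestStepDuality:
    @pytest.mark.parametrize("mode", ["linear", "titration"])
    def test_inner_product_identity_per_step(self, mode):
        """⟨L x, y⟩ = ⟨x, Lᵀ y⟩ for the full sub-step linearization."""
        model = _model(seed=1, mode=mode)
        rng = np.random.default_rng(2)
        shape = (model.species.n_species, model.grid.ny, model.grid.nx)
        # linearize about a realistic non-negative state
        base = rng.uniform(0, 20, shape)
        _, rec = model.substep(base, np.zeros(shape), 3)
        for _ in range(5):
            x = rng.standard_normal(shape)
            y = rng.standard_normal(shape)
            lhs = float((model.substep_linear(x, rec, 3) * y).sum())
            rhs = float((x * model.substep_transpose(y, rec, 3)).sum())
            assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_zero_forcing_gives_zero_sensitivity(self):
        model = _model()
        g = model.grid
        emis = np.zeros((model.species.n_species, g.n_hours, g.ny, g.nx))
        traj, recs = model.run(emis, keep_records=True)
        forcing = np.zeros((g.n_hours, g.ny, g.nx))
        sens = run_adjoint(model, traj, recs, forcing)
        assert np.all(sens.values == 0)

    def test_adjoint_advection_moves_influence_upwind(self):
        """Uniform eastward wind: a receptor's influence spreads westward in
        the backward run — upwind cells acquire sensitivity."""
        model = _model(wind=(8.0, 0.0), diff=0.0, seed=3)
        # remove wind noise: strictly eastward
        model.met.u[:] = 8.0
        model.met.v[:] = 0.0
        model._adv_cache.clear()
        model._adv_cache_T.clear()
        g = model.grid
        emis = np.zeros((model.species.n_species, g.n_hours, g.ny, g.nx))
        traj, recs = model.run(emis, keep_records=True)
        forcing = np.zeros((g.n_hours, g.ny, g.nx))
        rx, ry = 4, 2
        forcing[-1, ry, rx] = 1.0
        sens = run_adjoint(model, traj, recs, forcing)
        ec = sens.select("EC")
        assert ec[-1, ry, rx] > 0           # the receptor cell itself
        assert ec[-2, ry, rx - 1] > 0       # one cell west, one hour earlier
        assert ec[:, ry, rx + 1:].max() == 0  # strictly downwind: unreachable


class TestBoxClosedForm:
    def test_geometric_series(self, box_world):
        """1x1 box, exponential loss k, constant hourly forcing φ: the
        sensitivity to emission in hour n is the geometric series
        conv·φ·e^{-k}·(1 - e^{-k(N-n)})/(1 - e^{-k}) — the e^{-k} prefactor
        because an emission is deposited within its own (operator-split)
        hour."""
        w = box_world
        model = w.model()
        traj, recs = model.run(w.emissions(), 0, keep_records=True)
        g = w.grid
        phi = 0.37  # deaths per (μg/m³), arbitrary constant forcing
        forcing = np.full((g.n_hours, 1, 1), phi)
        sens = run_adjoint(model, traj, recs, forcing)
        k = w.species.deposition_per_h["EC"]
        conv = 1e12 / g.cell_volume_m3
        ec = sens.select("EC")[:, 0, 0]
        n = np.arange(g.n_hours)
        expected = conv * phi * np.exp(-k) * (1 - np.exp(-k * (g.n_hours - n))) \
            / (1 - np.exp(-k))
        np.testing.assert_allclose(ec, expected, rtol=1e-10)

    def test_scales_linearly_with_forcing(self, box_world):
        w = box_world
        model = w.model()
        traj, recs = model.run(w.emissions(), 0, keep_records=True)
        g = w.grid
        f1 = np.full((g.n_hours, 1, 1), 1.0)
        s1 = run_adjoint(model, traj, recs, f1).values
        s3 = run_adjoint(model, traj, recs, 3.0 * f1).values
        np.testing.assert_allclose(s3, 3.0 * s1, rtol=1e-13)


class TestCausalityAndChannels:
    def test_downwind_cells_have_zero_sensitivity(self, plume_world):
        """Zero-inflow boundary, uniform eastward wind: cells strictly east of
        the populated receptor cannot influence it."""
        w = plume_world
        model = w.model()
        traj, recs = model.run(w.emissions(), 0, keep_records=True)
        cost = GemmCost(w.panel, w.gemm)
        forcing = hourly_forcing(traj, cost)
        sens = run_adjoint(model, traj, recs, forcing)
        pop = w.panel.population
        ry, rx = np.unravel_index(np.argmax(pop), pop.shape)
        assert sens.values[:, :, :, rx + 1:].max() == 0
        assert sens.select("EC")[:, ry, rx - 3].max() > 0

    def test_so2_sensitivity_flows_through_sulfate_channel(self):
        """Forcing on PM species only: SO2 emissions matter only via the
        SO2→pSO4 conversion; with that rate zeroed the sensitivity vanishes."""
        species = SpeciesSet()
        convs = tuple(
            type(c)(c.gas, c.particle, 0.0 if c.gas == "SO2" else c.rate_per_h)
            for c in species.conversions)
        no_so4 = SpeciesSet(conversions=convs)
        for sp in (species, no_so4):
            grid = GridSpec(4, 4, n_hours=6)
            nh = grid.n_hours
            met = MetFields(np.zeros((nh, 4, 4)), np.zeros((nh, 4, 4)),
                            np.ones((nh, len(sp.conversions))))
            model = ForwardModel(grid, sp, met)
            emis = np.zeros((sp.n_species, nh, 4, 4))
            traj, recs = model.run(emis, keep_records=True)
            forcing = np.ones((nh, 4, 4))
            sens = run_adjoint(model, traj, recs, forcing)
            if sp is species:
                assert sens.select("SO2").max() > 0
            else:
                assert sens.select("SO2").max() == 0
            assert sens.select("PSO4").max() > 0  # direct PM species always forced


class TestGlobalDuality:
    def test_gradient_equals_forward_response_linear_cost(self):
        """⟨∂J/∂E, δE⟩ = J(E+δE) − J(E) exactly for linear chemistry+cost."""
        model = _model(seed=4)
        g = model.grid
        rng = np.random.default_rng(5)
        shape = (model.species.n_species, g.n_hours, g.ny, g.nx)
        E = rng.uniform(0, 2, shape)
        dE = rng.uniform(0, 0.5, shape)
        weights = rng.uniform(0, 1, (g.ny, g.nx))
        cost = LinearCost(weights)
        traj, recs = model.run(E, keep_records=True)
        forcing = hourly_forcing(traj, cost)
        sens = run_adjoint(model, traj, recs, forcing)
        pred = float((sens.values * dE).sum())
        j0 = cost.value(model.run(E).exposure_mean())
        j1 = cost.value(model.run(E + dE).exposure_mean())
        assert pred == pytest.approx(j1 - j0, rel=1e-8)

    def test_directional_derivative_gemm_cost(self):
        """With the nonlinear GEMM cost the adjoint gradient matches the
        central-difference directional derivative as the step shrinks."""
        model = _model(seed=6)
        g = model.grid
        rng = np.random.default_rng(7)
        shape = (model.species.n_species, g.n_hours, g.ny, g.nx)
        E = rng.uniform(0, 40, shape)
        dE = rng.uniform(0, 1, shape)
        from pmadjoint import ExposurePanel
        panel = ExposurePanel(rng.uniform(1e4, 1e6, (g.ny, g.nx)),
                              np.full((g.ny, g.nx), 0.01))
        cost = GemmCost(panel)
        traj, recs = model.run(E, keep_records=True)
        forcing = hourly_forcing(traj, cost)
        sens = run_adjoint(model, traj, recs, forcing)
        pred = float((sens.values * dE).sum())
        eps = 1e-3
        jp = cost.value(model.run(E + eps * dE).exposure_mean())
        jm = cost.value(model.run(E - eps * dE).exposure_mean())
        assert pred == pytest.approx((jp - jm) / (2 * eps), rel=1e-6)

    def test_nonnegative_sensitivities_in_linear_mode(self, default_world):
        from pmadjoint.validation import deaths_sensitivity_field
        sens = deaths_sensitivity_field(default_world)
        assert sens.values.min() >= 0


class TestEmissionWeighting:
    def _sens(self, values, species, grid):
        return SensitivityField(values, species, grid)

    def test_equal_sensitivities_unchanged(self):
        species = SpeciesSet()
        grid = GridSpec(2, 2, n_hours=3)
        vals = np.zeros((species.n_species, 3, 2, 2))
        idx = species.indices(species.primary)
        vals[idx] = 7.5
        emis = np.random.default_rng(0).uniform(0, 2, vals.shape)
        agg = emission_weighted_primary_pm(self._sens(vals, species, grid), emis)
        np.testing.assert_allclose(agg, 7.5, rtol=1e-14)

    def test_weighted_mean_arithmetic(self):
        """Sensitivities (10, 20) deaths/kton with emissions (3, 1) tons
        aggregate to 12.5 deaths/kton."""
        species = SpeciesSet(primary=("EC", "OC"),
                             deposition_per_h={"EC": 0.0, "OC": 0.0})
        grid = GridSpec(1, 1, n_hours=1)
        vals = np.zeros((species.n_species, 1, 1, 1))
        vals[species.index("EC")] = 10.0
        vals[species.index("OC")] = 20.0
        emis = np.zeros_like(vals)
        emis[species.index("EC")] = 3.0
        emis[species.index("OC")] = 1.0
        agg = emission_weighted_primary_pm(self._sens(vals, species, grid), emis)
        assert agg[0, 0, 0] == pytest.approx(12.5, rel=1e-14)

    def test_invariant_to_rescaling_emissions(self):
        species = SpeciesSet()
        grid = GridSpec(3, 3, n_hours=2)
        rng = np.random.default_rng(1)
        vals = rng.uniform(0, 5, (species.n_species, 2, 3, 3))
        emis = rng.uniform(0.1, 2, vals.shape)
        a1 = emission_weighted_primary_pm(self._sens(vals, species, grid), emis)
        a2 = emission_weighted_primary_pm(self._sens(vals, species, grid),
                                          4.2 * emis)
        np.testing.assert_allclose(a1, a2, rtol=1e-13)

    def test_zero_emission_cells_use_unweighted_mean(self):
        species = SpeciesSet()
        grid = GridSpec(1, 1, n_hours=1)
        vals = np.zeros((species.n_species, 1, 1, 1))
        idx = species.indices(species.primary)
        vals[idx, 0, 0, 0] = [3.0, 6.0, 9.0]
        emis = np.zeros_like(vals)
        agg = emission_weighted_primary_pm(self._sens(vals, species, grid), emis)
        assert agg[0, 0, 0] == pytest.approx(6.0, rel=1e-14)
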