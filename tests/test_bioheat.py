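"""Solver-level tests: source normalisation, Pennes term, conservation,
closed-form limits and an independent analytic validation of the scheme."""

import numpy as np
import pytest

from enafl.bioheat import (LaserSource, SigmaConvention, SimGrid,
                           TemperatureField, ThermalProperties,
                           TissueGeometry, annulus_source_powers,
                           bioheat_source_term, cell_volumes,
                           deposited_energy, enthalpy_above_blood, evolve,
                           simulate, step_temperature, surface_flux_profile)
from conftest import coarse_grid


@pytest.fixture()
def grid(thin_geometry):
    return coarse_grid(thin_geometry)


class TestSurfaceFlux:
    def test_flux_integrates_to_laser_power(self, source, thin_geometry):
        """2 pi int q(r) r dr recovers the 35 mW beam power."""
        grid = SimGrid.build(thin_geometry)   # source-resolving resolution
        q = surface_flux_profile(source, grid)
        total = 2.0 * np.pi * np.trapezoid(q * grid.r, grid.r)
        assert total == pytest.approx(source.power, rel=1e-3)

    def test_annulus_powers_sum_exactly_to_power(self, source, grid):
        Q = annulus_source_powers(source, grid)
        assert Q.sum() == pytest.approx(source.power, rel=1e-12)

    def test_one_dimensional_marginal_mass_is_99_7_percent(self, source):
        """The stated beam diameter spans +-3 sigma of the line profile and
        so carries 99.7% of the power along a cut through the centre."""
        from scipy.integrate import quad
        # in units of sigma the marginal is the standard Gaussian
        marginal = lambda u: np.exp(-u ** 2 / 2)
        inside, _ = quad(marginal, -3, 3)
        total, _ = quad(marginal, -12, 12)
        assert inside / total == pytest.approx(0.997, abs=5e-4)

    def test_centre_amplitude_matches_quadrature_oracle(self, source, grid):
        """A = P / (2 pi sigma^2) agrees with normalising a sampled Gaussian
        by numerical quadrature on the same radial grid."""
        from scipy.integrate import simpson
        sigma = source.sigma
        r_dense = np.linspace(0, grid.r[-1], 20001)
        shape = np.exp(-r_dense ** 2 / (2 * sigma ** 2))
        amplitude_oracle = source.power / (
            2 * np.pi * simpson(shape * r_dense, x=r_dense))
        q = surface_flux_profile(source, grid)
        assert q[0] == pytest.approx(amplitude_oracle, rel=1e-3)

    def test_sigma_conventions(self):
        s6 = LaserSource()
        s3 = LaserSource(sigma_convention=SigmaConvention.DIAMETER_IS_3_SIGMA)
        assert s6.sigma == pytest.approx(s6.beam_diameter / 6)
        assert s3.sigma == pytest.approx(2 * s6.sigma)

    def test_under_resolved_source_rejected(self, thin_geometry):
        grid = SimGrid.build(thin_geometry, dr_core=40e-6, core_radius=4e-4)
        with pytest.raises(ValueError, match="under-resolved"):
            surface_flux_profile(LaserSource(), grid)


class TestPennesTerm:
    def test_equilibrium_leaves_only_metabolic_heat(self, props, grid):
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), props.blood_temperature), time=0)
        np.testing.assert_allclose(bioheat_source_term(props, field),
                                   props.metabolic_heat)

    def test_zero_perfusion_zero_metabolism_vanishes(self, grid):
        p = ThermalProperties(perfusion_rate=0.0, metabolic_heat=0.0)
        field = TemperatureField(T=np.full((grid.n_z, grid.n_r), 55.0), time=0)
        np.testing.assert_array_equal(bioheat_source_term(p, field), 0.0)

    def test_hot_tissue_is_cooled_by_perfusion(self, grid):
        """10 degC above blood gives -rho_b c_b omega_b * 10 (a heat sink)."""
        p = ThermalProperties(metabolic_heat=0.0)
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), p.blood_temperature + 10.0),
            time=0)
        expected = -1050.0 * 3617.0 * 1.0e-3 * 10.0
        np.testing.assert_allclose(bioheat_source_term(p, field), expected)


class TestStepping:
    def test_uniform_blood_temperature_is_steady(self, grid, source):
        """No laser, T = T_b, Q_m = 0: exact steady state of the scheme."""
        p = ThermalProperties(metabolic_heat=0.0)
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), p.blood_temperature), time=0.0)
        out = step_temperature(field, p, source, grid, laser_on=False)
        np.testing.assert_allclose(out.T, field.T, atol=1e-10)

    def test_single_step_perfusion_decay_factor(self, grid, source):
        """k = 0: one implicit step divides the uniform excess by
        (1 + a dt), within O(dt^2) of exp(-a dt)."""
        p = ThermalProperties(conductivity=0.0, metabolic_heat=0.0)
        dt = 0.01
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), p.blood_temperature + 5.0),
            time=0.0)
        out = step_temperature(field, p, source, grid, laser_on=False, dt=dt)
        a = p.perfusion_decay_rate
        excess = out.T - p.blood_temperature
        np.testing.assert_allclose(excess, 5.0 * np.exp(-a * dt),
                                   rtol=(a * dt) ** 2)

    def test_one_heating_step_deposits_p_dt(self, grid, source):
        p = ThermalProperties(perfusion_rate=0.0, metabolic_heat=0.0)
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), p.blood_temperature), time=0.0)
        dt = 0.01
        out = step_temperature(field, p, source, grid, laser_on=True, dt=dt)
        gained = enthalpy_above_blood(out, p, grid)
        assert gained == pytest.approx(source.power * dt, rel=1e-2)

    def test_perfusion_decay_closed_form_over_ten_seconds(self, thin_geometry,
                                                          source):
        """k = 0, +10 degC uniform offset decays as exp(-rho_b c_b omega_b
        t / (rho cp)) within 0.1% over 10 s at dt = 10 ms."""
        p = ThermalProperties(conductivity=0.0, metabolic_heat=0.0)
        grid = coarse_grid(thin_geometry)
        field = TemperatureField(
            T=np.full((grid.n_z, grid.n_r), p.blood_temperature + 10.0),
            time=0.0)
        out = evolve(field, p, source, grid, duration=10.0, laser_on=False,
                     dt=0.01)
        expected = 10.0 * np.exp(-p.perfusion_decay_rate * 10.0)
        np.testing.assert_allclose(out.T - p.blood_temperature, expected,
                                   rtol=1e-3)


class TestSimulate:
    def test_no_power_stays_at_blood_temperature(self, thin_geometry):
        p = ThermalProperties(metabolic_heat=0.0)
        hist = simulate(p, thin_geometry, LaserSource(power=0.0),
                        coarse_grid(thin_geometry), t_end=3.0)
        for snap in hist:
            np.testing.assert_allclose(snap.T, p.blood_temperature,
                                       atol=1e-8)

    def test_first_snapshot_is_initial_condition(self, thin_history, props):
        first = thin_history.snapshots[0]
        assert first.time == 0.0
        np.testing.assert_array_equal(first.T, props.blood_temperature)

    def test_snapshot_times_increase_and_include_heating_end(self,
                                                             thin_history,
                                                             source):
        times = thin_history.times
        assert np.all(np.diff(times) > 0)
        assert source.on_time in times

    def test_t_end_before_heating_end_rejected(self, props, thin_geometry,
                                               source):
        with pytest.raises(ValueError, match="t_end"):
            simulate(props, thin_geometry, source,
                     coarse_grid(thin_geometry), t_end=1.0)

    def test_grid_geometry_mismatch_rejected(self, props, thin_geometry,
                                             thick_geometry, source):
        with pytest.raises(ValueError, match="geometry"):
            simulate(props, thin_geometry, source,
                     coarse_grid(thick_geometry))

    def test_energy_conservation_with_insulated_boundaries(
            self, thin_noperf_history, source):
        """All boundaries insulated, no perfusion: enthalpy at the end of
        heating equals the 70 mJ optical energy within 1%."""
        p = ThermalProperties(perfusion_rate=0.0, metabolic_heat=0.0)
        grid = thin_noperf_history.grid
        idx = int(np.argmin(np.abs(thin_noperf_history.times
                                   - source.on_time)))
        snap = thin_noperf_history.snapshots[idx]
        assert snap.time == pytest.approx(source.on_time)
        gained = enthalpy_above_blood(snap, p, grid)
        assert gained == pytest.approx(deposited_energy(source), rel=1e-2)

    def test_semi_infinite_closed_form_validation(self, thick_geometry,
                                                  source):
        """Before the boundaries are felt, the thick slab matches the
        textbook semi-infinite Gaussian-flux solution
        T(t) = (q0 sigma / k) sqrt(2/pi) arctan(sqrt(2 alpha t)/sigma)."""
        p = ThermalProperties(perfusion_rate=0.0, metabolic_heat=0.0)
        grid = SimGrid.build(thick_geometry, dt=2.5e-3)
        hist = simulate(p, thick_geometry, source, grid, t_end=2.0)
        alpha = p.diffusivity
        q0 = source.power / (2 * np.pi * source.sigma ** 2)
        for snap in hist:
            if snap.time < 0.25:
                continue
            analytic = (p.blood_temperature
                        + (q0 * source.sigma / p.conductivity)
                        * np.sqrt(2 / np.pi)
                        * np.arctan(np.sqrt(2 * alpha * snap.time)
                                    / source.sigma))
            rise = snap.T[0, 0] - p.blood_temperature
            assert rise == pytest.approx(analytic - p.blood_temperature,
                                         rel=7e-3)

    def test_maximum_principle_during_cooling(self, thin_noperf_history,
                                              source):
        """With the source off and no heat generation the spatial maximum
        cannot grow."""
        maxima = [(s.time, s.T.max()) for s in thin_noperf_history
                  if s.time >= source.on_time]
        values = [m for _, m in maxima]
        assert all(b <= a + 1e-9 for a, b in zip(values, values[1:]))

    def test_spatial_peak_sits_on_the_axis_during_heating(self,
                                                          thin_history,
                                                          source):
        for snap in thin_history:
            if 0 < snap.time <= source.on_time:
                surface = snap.T[0]
                assert surface[0] == pytest.approx(surface.max())

    def test_thin_slab_runs_hotter_than_thick(self, thin_history,
                                              thick_history):
        assert (max(s.T.max() for s in thin_history)
                > max(s.T.max() for s in thick_history))

    def test_crank_nicolson_agrees_with_backward_euler(self, props,
                                                       thin_geometry,
                                                       source):
        grid = coarse_grid(thin_geometry, dt=0.01)
        be = simulate(props, thin_geometry, source, grid, t_end=2.0)
        cn = simulate(props, thin_geometry, source, grid, t_end=2.0,
                      theta=0.5)
        peak_be = max(s.T.max() for s in be)
        peak_cn = max(s.T.max() for s in cn)
        assert peak_cn == pytest.approx(peak_be, rel=2e-2)


class TestDose:
    def test_seventy_millijoule_dose(self):
        assert deposited_energy(LaserSource()) == pytest.approx(70e-3)

    def test_zero_power_zero_energy(self):
        assert deposited_energy(LaserSource(power=0.0)) == 0.0

    def test_energy_linear_in_time(self):
        assert deposited_energy(LaserSource(on_time=1.0)) == \
            pytest.approx(35e-3)

    def test_protocol_accounts_four_spots(self):
        from enafl.bioheat import IrradiationProtocol
        proto = IrradiationProtocol()
        assert proto.spots == 4
        assert proto.energy_per_spot == pytest.approx(70e-3)
        assert proto.total_energy == pytest.approx(280e-3)


class TestInvariants:
    def test_properties_validated(self):
        with pytest.raises(ValueError):
            ThermalProperties(density=-1.0)
        with pytest.raises(ValueError):
            ThermalProperties(perfusion_rate=-1e-3)

    def test_geometry_validated(self):
        with pytest.raises(ValueError):
            TissueGeometry(radius=0.0)

    def test_non_finite_field_rejected(self):
        with pytest.raises(ValueError, match="finite"):
            TemperatureField(T=np.array([[np.nan, 1.0]]), time=0.0)

    def test_cell_volumes_tile_the_cylinder(self, thin_geometry):
        grid = coarse_grid(thin_geometry)
        vols = cell_volumes(grid)
        expected = np.pi * thin_geometry.radius ** 2 * thin_geometry.thickness
        assert vols.sum() == pytest.approx(expected, rel=1e-12)
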