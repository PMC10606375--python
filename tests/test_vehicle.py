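"""Donor-vehicle models: dissolution law, phase splits, conservation."""

import math

import numpy as np
import pytest

from dermasim import units
from dermasim.core import DomainError
from dermasim.vehicle import (EmulsionParams, SolutionParams, SuspensionParams,
                              VehicleGeometry, build_vehicle_model,
                              dissolution_flux, update_particle_geometry,
                              vehicle_rhs)


def small_geometry(**kw):
    defaults = dict(n_cells=10, grid_ratio=1.2)
    defaults.update(kw)
    return VehicleGeometry(**defaults)


class TestDissolutionFlux:
    def test_saturation_gives_zero(self):
        assert dissolution_flux(1e6, 1e-10, 1e-11, 0.63, 0.63, 1e-6) == 0.0

    def test_direct_evaluation(self):
        sa = 4 * math.pi * (1e-6) ** 2   # 1.2566e-11 m^2
        j = dissolution_flux(1, 1e-10, sa, 1.0, 0.0, 1e-6)
        assert j == pytest.approx(1.2566e-15, rel=1e-4)

    def test_linear_in_particle_number(self):
        j1 = dissolution_flux(1e3, 1e-10, 1e-11, 1.0, 0.2, 1e-6)
        j2 = dissolution_flux(2e3, 1e-10, 1e-11, 1.0, 0.2, 1e-6)
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_zero_radius_guard(self):
        with pytest.raises(DomainError):
            dissolution_flux(1e3, 1e-10, 1e-11, 1.0, 0.2, 0.0)


class TestParticleGeometry:
    def test_cube_root_scaling(self):
        r1, sa1 = update_particle_geometry(8e-9, 1e3, 1300.0)
        r2, sa2 = update_particle_geometry(1e-9, 1e3, 1300.0)
        assert r2 == pytest.approx(r1 / 2, rel=1e-12)
        assert sa2 == pytest.approx(sa1 / 4, rel=1e-12)

    def test_exhaustion(self):
        assert update_particle_geometry(0.0, 1e3, 1300.0) == (0.0, 0.0)

    def test_reference_diameter_inversion(self):
        # mass that makes 1000 particles of density 1300 have r = 1.685 um
        r_target = 1.685e-6
        m = 1000 * (4 / 3) * math.pi * r_target ** 3 * 1300.0
        r, _ = update_particle_geometry(m, 1000, 1300.0)
        assert 2 * r == pytest.approx(3.37e-6, rel=1e-12)

    def test_negative_mass_rejected(self):
        with pytest.raises(DomainError):
            update_particle_geometry(-1e-9, 1e3, 1300.0)


class TestInitialPartition:
    def test_suspension_saturation_split(self):
        # 1250 ug in 0.64 cm^2 x 0.92 cm = 0.5888 mL with Cs = 0.63 mg/mL
        model = build_vehicle_model("suspension", small_geometry(),
                                    SuspensionParams())
        y = model.initial_state()
        n = model.n_cells
        dissolved_mg = y[:n].sum() / units.MG
        solid_mg = y[n:].sum() / units.MG
        assert dissolved_mg == pytest.approx(0.63 * 0.5888, rel=1e-6)
        assert dissolved_mg + solid_mg == pytest.approx(1.25, rel=1e-12)
        # uniform concentration at saturation
        conc = y[:n] / model.cont_volumes
        assert np.allclose(conc, 0.63, rtol=1e-9)

    def test_solution_has_no_dispersed_phase(self):
        model = build_vehicle_model("solution", small_geometry(), SolutionParams())
        assert model.n_states == model.n_cells
        y = model.initial_state()
        assert y.sum() == pytest.approx(1250 * units.UG, rel=1e-12)

    def test_emulsion_symmetric_equilibrium(self):
        params = EmulsionParams(kp_cont_disp=1.0, dispersed_volume_fraction=0.5)
        model = build_vehicle_model("emulsion", small_geometry(), params)
        y = model.initial_state()
        n = model.n_cells
        c_cont = y[:n] / model.cont_volumes
        c_disp = y[n:] / (0.5 * model.cell_volumes)
        assert np.allclose(c_cont, c_disp, rtol=1e-12)

    def test_emulsion_table_orientation(self):
        # continuous/dispersed partition 4.484: continuous phase is richer
        model = build_vehicle_model("emulsion", small_geometry(), EmulsionParams())
        y = model.initial_state()
        n = model.n_cells
        c_cont = y[0] / model.cont_volumes[0]
        c_disp = y[n] / (0.2 * model.cell_volumes[0])
        assert c_cont / c_disp == pytest.approx(4.484, rel=1e-9)

    def test_kind_parameter_mismatch_rejected(self):
        with pytest.raises(DomainError):
            build_vehicle_model("suspension", small_geometry(), EmulsionParams())


class TestClosedVehicleDynamics:
    @pytest.mark.parametrize("kind, params", [
        ("solution", SolutionParams()),
        ("emulsion", EmulsionParams()),
        ("suspension", SuspensionParams()),
    ])
    def test_mass_conserved_over_a_day(self, kind, params):
        model = build_vehicle_model(kind, small_geometry(), params)
        _, states = model.simulate_closed(24 * units.HOUR, n_out=10)
        totals = states.sum(axis=1)
        assert np.allclose(totals, totals[0], rtol=1e-9)

    def test_suspension_saturation_clamp(self):
        model = build_vehicle_model("suspension", small_geometry(),
                                    SuspensionParams())
        _, states = model.simulate_closed(12 * units.HOUR, n_out=20)
        conc = states[:, :model.n_cells] / model.cont_volumes
        assert conc.max() <= 0.63 * (1 + 1e-6)

    def test_emulsion_relaxes_to_analytic_equilibrium(self):
        params = EmulsionParams()
        model = build_vehicle_model("emulsion", small_geometry(), params)
        n = model.n_cells
        # perturb: push everything into the droplets
        y0 = model.initial_state()
        total = y0.sum()
        y0_pert = np.zeros_like(y0)
        y0_pert[n:] = total * model.cell_volumes / model.cell_volumes.sum()
        _, states = model.simulate_closed(24 * units.HOUR, state0=y0_pert, n_out=5)
        phi, kp = params.dispersed_volume_fraction, params.kp_cont_disp
        cont_frac_expected = kp * (1 - phi) / (kp * (1 - phi) + phi)
        cont_frac = states[-1, :n].sum() / total
        assert cont_frac == pytest.approx(cont_frac_expected, rel=1e-6)
        assert states[-1].sum() == pytest.approx(total, rel=1e-9)

    def test_infinite_solubility_matches_solution_model(self):
        geo = small_geometry()
        susp = build_vehicle_model("suspension", geo,
                                   SuspensionParams(solubility=1e9,
                                                    diff_vehicle=1e-10))
        sol = build_vehicle_model("solution", geo,
                                  SolutionParams(diff_vehicle=1e-10))
        ys, yl = susp.initial_state(), sol.initial_state()
        assert np.allclose(ys[:geo.n_cells], yl)      # all drug dissolved
        assert ys[geo.n_cells:].sum() == 0.0
        ds = vehicle_rhs(susp, ys, 0.0)
        dl = vehicle_rhs(sol, yl, 0.0)
        assert np.allclose(ds[:geo.n_cells], dl, atol=1e-30)


class TestVehicleRhsContract:
    def test_equilibrium_initial_state_is_steady(self):
        model = build_vehicle_model("emulsion", small_geometry(), EmulsionParams())
        y = model.initial_state()
        dy = vehicle_rhs(model, y, 0.0)
        scale = y.max() / (24 * units.HOUR)
        assert np.abs(dy).max() < 1e-9 * scale

    def test_derivatives_sum_to_minus_boundary_flux(self):
        model = build_vehicle_model("suspension", small_geometry(),
                                    SuspensionParams())
        y = model.initial_state() * 0.7
        flux = 3.3e-13
        dy = vehicle_rhs(model, y, flux)
        assert dy.sum() == pytest.approx(-flux, rel=1e-9)

    def test_empty_vehicle_starts_with_pure_dissolution(self):
        model = build_vehicle_model("suspension", small_geometry(),
                                    SuspensionParams())
        y = model.initial_state()
        n = model.n_cells
        y_dry = np.concatenate([np.zeros(n), y[:n] + y[n:]])
        model2 = build_vehicle_model("suspension", small_geometry(),
                                     SuspensionParams())
        model2.initial_state()
        model2.particle_number_per_cell = (
            y_dry[n:] / ((math.pi / 6) * (3.37e-6) ** 3 * 1300.0))
        dy = vehicle_rhs(model2, y_dry, 0.0)
        # with Cv = 0 everywhere the only source is dissolution, cell by cell
        from dermasim.vehicle import update_particle_geometry as upg
        for i in range(n):
            npc = model2.particle_number_per_cell[i]
            r, sa = upg(y_dry[n + i], npc, 1300.0)
            expected = npc * 1e-10 * sa * 0.63 / r
            assert dy[i] == pytest.approx(expected, rel=1e-9)
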