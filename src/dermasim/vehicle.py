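"""Mechanistic donor-vehicle (formulation) models.

Three vehicle kinds produce the source flux into the barrier-facing boundary
of a Franz cell:

* ``solution``  - single aqueous phase, pure 1-D diffusion;
* ``emulsion``  - cream: oil droplets dispersed in a continuous aqueous
  phase.  Droplet <-> continuous exchange uses the generic interface-flux law
  with the total droplet surface area per cell and the continuous/dispersed
  partition coefficient;
* ``suspension`` - ointment: solid drug particles in an oily base dissolving
  by the Nernst-Brunner modification of the Noyes-Whitney law,
  J = Np * Dp * SAp * (Cs - Cv) / Rp, with monodisperse shrinking spheres.

The vehicle film (default 0.92 cm) is far thicker than the diffusion depth
over a day, so it is discretised into 1-D finite volumes refined toward the
barrier face rather than treated as well mixed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Union

import numpy as np
from scipy.integrate import solve_ivp

from . import units
from .core import DomainError, _check_nonnegative, _check_positive, geometric_widths
from .network import FluxNetwork

_RADIUS_FLOOR = 1e-9  # m; stiffness guard at particle exhaustion


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class VehicleGeometry:
    thickness: float = 0.92 * units.CM          # m
    initial_drug_mass: float = 1250 * units.UG  # kg
    contact_area: float = 0.64 * units.CM2      # m^2
    n_cells: int = 40
    grid_ratio: float = 1.2                     # geometric refinement toward barrier

    def __post_init__(self) -> None:
        _check_positive(thickness=self.thickness, contact_area=self.contact_area)
        _check_nonnegative(initial_drug_mass=self.initial_drug_mass)
        if self.n_cells < 1:
            raise DomainError("vehicle needs at least one cell")

    @property
    def volume(self) -> float:
        return self.thickness * self.contact_area


@dataclass(frozen=True)
class EmulsionParams:
    """Cream: oil-in-water two-phase parameters."""
    droplet_diameter: float = 3.37 * units.UM
    kp_cont_disp: float = 4.484        # C_continuous/C_dispersed at equilibrium
    diff_continuous: float = 0.85e-10  # m^2/s
    dispersed_volume_fraction: float = 0.2
    kp_vehicle_receptor: float = 223.872

    def __post_init__(self) -> None:
        _check_positive(droplet_diameter=self.droplet_diameter,
                        kp_cont_disp=self.kp_cont_disp,
                        diff_continuous=self.diff_continuous,
                        kp_vehicle_receptor=self.kp_vehicle_receptor)
        if not (0.0 < self.dispersed_volume_fraction < 1.0):
            raise DomainError("dispersed_volume_fraction must lie in (0, 1)")


@dataclass(frozen=True)
class SuspensionParams:
    """Ointment: solid particles suspended in an oily continuous base."""
    particle_diameter: float = 3.37 * units.UM
    solubility: float = 0.63           # kg/m^3 (mg/mL) in the continuous phase
    diff_vehicle: float = 1e-10        # m^2/s, also Dp at the particle surface
    particle_density: float = 1300.0   # kg/m^3
    kp_vehicle_receptor: float = 223.872
    shrinking_particles: bool = True

    def __post_init__(self) -> None:
        _check_positive(particle_diameter=self.particle_diameter,
                        solubility=self.solubility,
                        diff_vehicle=self.diff_vehicle,
                        particle_density=self.particle_density,
                        kp_vehicle_receptor=self.kp_vehicle_receptor)


@dataclass(frozen=True)
class SolutionParams:
    diff_vehicle: float = 1e-9         # m^2/s, aqueous-like control
    kp_vehicle_receptor: float = 1.0

    def __post_init__(self) -> None:
        _check_positive(diff_vehicle=self.diff_vehicle,
                        kp_vehicle_receptor=self.kp_vehicle_receptor)


VehicleParams = Union[EmulsionParams, SuspensionParams, SolutionParams]


# ---------------------------------------------------------------------------
# elemental operations
# ---------------------------------------------------------------------------

def dissolution_flux(particle_number: float, diff_p: float, surface_area_p: float,
                     solubility: float, conc_vehicle: float, radius_p: float) -> float:
    """Nernst-Brunner dissolution flux J = Np*Dp*SAp*(Cs - Cv)/Rp in kg/s.

    ``surface_area_p`` is the per-particle surface area.  The flux is positive
    while the vehicle is undersaturated and vanishes at saturation.
    """
    _check_positive(particle_number=particle_number, diff_p=diff_p,
                    surface_area_p=surface_area_p, solubility=solubility)
    _check_nonnegative(conc_vehicle=conc_vehicle)
    if radius_p <= 0:
        raise DomainError("radius_p must be positive while solid mass remains "
                          "(numerical guard); clamp upstream")
    return particle_number * diff_p * surface_area_p * (solubility - conc_vehicle) / radius_p


def update_particle_geometry(solid_mass: float, particle_number: float,
                             particle_density: float) -> tuple[float, float]:
    """Radius and per-particle surface area of monodisperse shrinking spheres.

    r = (3 m / (4 pi rho Np))^(1/3),  SA = 4 pi r^2;  returns (0, 0) once the
    solid phase is exhausted.
    """
    if solid_mass < 0:
        raise DomainError(f"solid_mass must be non-negative, got {solid_mass!r}")
    _check_positive(particle_number=particle_number, particle_density=particle_density)
    if solid_mass == 0.0:
        return 0.0, 0.0
    r = (3.0 * solid_mass / (4.0 * math.pi * particle_density * particle_number)) ** (1.0 / 3.0)
    return r, 4.0 * math.pi * r * r


# ---------------------------------------------------------------------------
# the discretised vehicle
# ---------------------------------------------------------------------------

@dataclass
class VehicleModel:
    """Discretised donor formulation.  Cell 0 faces the barrier.

    State layout (amounts in kg): continuous-phase amounts per cell, followed
    by dispersed droplet amounts (emulsion) or solid particle masses
    (suspension).  The total over all states is the drug mass ledger.
    """
    kind: str
    geometry: VehicleGeometry
    params: VehicleParams
    widths: np.ndarray = field(init=False)
    cell_volumes: np.ndarray = field(init=False)
    cont_volumes: np.ndarray = field(init=False)
    particle_number_per_cell: np.ndarray | None = field(init=False, default=None)

    def __post_init__(self) -> None:
        g = self.geometry
        self.widths = np.asarray(
            geometric_widths(g.thickness, g.n_cells, g.grid_ratio, refine="start"))
        self.cell_volumes = self.widths * g.contact_area
        if self.kind == "emulsion":
            phi = self.params.dispersed_volume_fraction
            self.cont_volumes = (1.0 - phi) * self.cell_volumes
        else:
            self.cont_volumes = self.cell_volumes.copy()

    # -- sizes ---------------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return self.geometry.n_cells

    @property
    def n_states(self) -> int:
        return self.n_cells if self.kind == "solution" else 2 * self.n_cells

    @property
    def diff_continuous(self) -> float:
        return getattr(self.params, "diff_continuous", None) or self.params.diff_vehicle

    @property
    def kp_vehicle_receptor(self) -> float:
        return self.params.kp_vehicle_receptor

    # -- initial condition ---------------------------------------------------

    def initial_state(self) -> np.ndarray:
        m_total = self.geometry.initial_drug_mass
        vv = float(self.cell_volumes.sum())
        n = self.n_cells
        y = np.zeros(self.n_states)
        frac = self.cell_volumes / vv
        if self.kind == "solution":
            y[:n] = m_total * frac
        elif self.kind == "suspension":
            cs = self.params.solubility
            dissolved = min(cs * vv, m_total)
            y[:n] = dissolved * frac
            y[n:] = (m_total - dissolved) * frac
            solid0 = y[n:]
            vp = (math.pi / 6.0) * self.params.particle_diameter ** 3
            self.particle_number_per_cell = solid0 / (vp * self.params.particle_density)
        elif self.kind == "emulsion":
            phi = self.params.dispersed_volume_fraction
            kp = self.params.kp_cont_disp
            # equilibrium split: C_cont = kp * C_disp
            c_disp = m_total / (vv * (kp * (1.0 - phi) + phi))
            c_cont = kp * c_disp
            y[:n] = c_cont * self.cont_volumes
            y[n:] = c_disp * phi * self.cell_volumes
        else:
            raise DomainError(f"unknown vehicle kind {self.kind!r}")
        return y

    # -- network pieces (local indices) --------------------------------------

    def state_volumes(self) -> np.ndarray:
        n = self.n_cells
        vols = np.empty(self.n_states)
        vols[:n] = self.cont_volumes
        if self.kind == "emulsion":
            phi = self.params.dispersed_volume_fraction
            vols[n:] = phi * self.cell_volumes
        elif self.kind == "suspension":
            vols[n:] = 1.0  # mass-only states; never used as concentrations
        return vols

    def state_labels(self) -> list[str]:
        n = self.n_cells
        labels = [f"veh_cont[{i}]" for i in range(n)]
        if self.kind == "emulsion":
            labels += [f"veh_disp[{i}]" for i in range(n)]
        elif self.kind == "suspension":
            labels += [f"veh_solid[{i}]" for i in range(n)]
        return labels

    def internal_links(self) -> list[tuple[int, int, float, float, float]]:
        """(ia, ib, P, SA, kp) for all intra-vehicle linear exchanges."""
        links = []
        area = self.geometry.contact_area
        d = self.diff_continuous
        w = self.widths
        n = self.n_cells
        for i in range(n - 1):
            p = 2.0 * d / (w[i] + w[i + 1])
            links.append((i + 1, i, p, area, 1.0))  # toward the barrier face
        if self.kind == "emulsion":
            dd = self.params.droplet_diameter
            p_drop = self.params.diff_continuous / (dd / 2.0)
            phi = self.params.dispersed_volume_fraction
            for i in range(n):
                sa = 6.0 * phi * self.cell_volumes[i] / dd  # total droplet area
                # droplet (A) -> continuous (B); equilibrium C_cont = kp*C_disp
                links.append((n + i, i, p_drop, sa, self.params.kp_cont_disp))
        return links

    def nonlinear_rates(self, amounts: np.ndarray) -> np.ndarray:
        """Dissolution source terms (suspension only); zeros otherwise."""
        rates = np.zeros_like(amounts)
        if self.kind != "suspension":
            return rates
        n = self.n_cells
        p = self.params
        npc = self.particle_number_per_cell
        if npc is None:
            raise RuntimeError("initial_state() must be called before the RHS")
        m = np.maximum(amounts[n:], 0.0)
        cv = amounts[:n] / self.cont_volumes
        with np.errstate(invalid="ignore"):
            r = np.where(npc > 0,
                         (3.0 * m / (4.0 * math.pi * p.particle_density *
                                     np.maximum(npc, 1e-300))) ** (1.0 / 3.0),
                         0.0)
        if not p.shrinking_particles:
            r = np.where(m > 0, p.particle_diameter / 2.0, 0.0)
        sa = 4.0 * math.pi * r * r
        r_eff = np.maximum(r, _RADIUS_FLOOR)
        flux = npc * p.diff_vehicle * sa * (p.solubility - cv) / r_eff
        flux = np.where(m > 0, flux, np.minimum(flux, 0.0))
        rates[:n] += flux
        rates[n:] -= flux
        return rates

    # -- standalone dynamics --------------------------------------------------

    def build_network(self) -> FluxNetwork:
        net = FluxNetwork(self.state_volumes(), self.state_labels())
        for ia, ib, p, sa, kp in self.internal_links():
            net.add_link(ia, ib, p, sa, kp)
        net.freeze()
        return net

    def simulate_closed(self, duration: float, state0: np.ndarray | None = None,
                        n_out: int = 50, rtol: float = 1e-8,
                        atol: float = 1e-16) -> tuple[np.ndarray, np.ndarray]:
        """Integrate the closed vehicle (zero boundary flux)."""
        if state0 is None:
            state0 = self.initial_state()
        elif self.kind == "suspension" and self.particle_number_per_cell is None:
            self.initial_state()
        net = self.build_network()

        def rhs(t, y):
            return net.rhs_linear(y) + self.nonlinear_rates(y)

        ts = np.linspace(0.0, duration, n_out)
        sol = solve_ivp(rhs, (0.0, duration), state0, method="BDF", t_eval=ts,
                        rtol=rtol, atol=atol, jac_sparsity=self.jac_sparsity(net))
        if not sol.success:  # pragma: no cover
            raise RuntimeError(f"vehicle integration failed: {sol.message}")
        return sol.t, sol.y.T

    def jac_sparsity(self, net: FluxNetwork):
        import scipy.sparse as sp
        pat = net.jac_sparsity().tolil()
        if self.kind == "suspension":
            n = self.n_cells
            for i in range(n):
                pat[i, n + i] = 1
                pat[n + i, i] = 1
                pat[n + i, n + i] = 1
        return pat.tocsr()


def build_vehicle_model(kind: str, geometry: VehicleGeometry,
                        params: VehicleParams | float) -> VehicleModel:
    """Construct a vehicle model; a bare float is a solution diffusivity."""
    if isinstance(params, float):
        params = SolutionParams(diff_vehicle=params)
    expected = {"solution": SolutionParams, "emulsion": EmulsionParams,
                "suspension": SuspensionParams}
    if kind not in expected:
        raise DomainError(f"unknown vehicle kind {kind!r}")
    if not isinstance(params, expected[kind]):
        raise DomainError(f"{kind} vehicle requires {expected[kind].__name__}")
    model = VehicleModel(kind=kind, geometry=geometry, params=params)
    model.initial_state()  # materialise particle numbers and validate the split
    return model


def vehicle_rhs(model: VehicleModel, amounts: np.ndarray,
                boundary_flux: float) -> np.ndarray:
    """Time derivative of the vehicle state given the signed flux (kg/s)
    leaving the barrier-facing cell.  Internal exchanges conserve mass, so the
    derivatives sum to exactly ``-boundary_flux``."""
    net = model.build_network()
    dy = net.rhs_linear(np.asarray(amounts, dtype=float))
    dy += model.nonlinear_rates(np.asarray(amounts, dtype=float))
    dy[0] -= boundary_flux
    return dy
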