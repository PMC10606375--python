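"""Shared domain types and elemental interface-transport operators.

The whole simulator is a network of well-mixed compartments exchanging drug
across interfaces.  The flux across a single interface between compartments
A and B is

    J(A->B) = P * SA * (C_A - C_B / Kp),        P = 1 / (dA*Kp/D_A + dB/D_B)

where ``P`` is the interface permeability, ``SA`` the shared area, ``dX`` the
diffusion distance on side X, ``D_X`` the diffusivity, and ``Kp`` the partition
coefficient of the link.  The convention used throughout the package is that
equilibrium (zero flux) corresponds to ``C_B = Kp * C_A``: ``Kp`` is the
equilibrium concentration of the *receiving* phase relative to the *donating*
phase.  A table entry labelled "Kp (X/Y)" therefore plugs directly into a link
that carries drug from Y into X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence


class DomainError(ValueError):
    """A physically inadmissible argument or configuration value."""


def _check_positive(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value <= 0.0:
            raise DomainError(f"{name} must be positive and finite, got {value!r}")


def _check_nonnegative(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if not math.isfinite(value) or value < 0.0:
            raise DomainError(f"{name} must be non-negative and finite, got {value!r}")


# ---------------------------------------------------------------------------
# elemental operators
# ---------------------------------------------------------------------------

def series_permeability(delta_a: float, diff_a: float, delta_b: float,
                        diff_b: float, kp_ab: float) -> float:
    """Two-film series permeability  P = 1/(dA*Kp/DA + dB/DB)  in m/s.

    ``delta_a``/``delta_b`` are the diffusion distances of the two films (m),
    ``diff_a``/``diff_b`` their diffusivities (m^2/s) and ``kp_ab`` the
    partition coefficient of the link.  P decreases in either film thickness
    and in Kp, and increases in either diffusivity.
    """
    _check_positive(delta_a=delta_a, diff_a=diff_a, delta_b=delta_b,
                    diff_b=diff_b, kp_ab=kp_ab)
    return 1.0 / (delta_a * kp_ab / diff_a + delta_b / diff_b)


def interface_flux(permeability: float, area: float, conc_a: float,
                   conc_b: float, kp_ab: float) -> float:
    """Diffusive interface flux  J = P*SA*(C_A - C_B/Kp)  in kg/s.

    Positive flux carries drug from A to B; the flux vanishes exactly at
    partition equilibrium ``C_A = C_B/Kp``.
    """
    _check_positive(permeability=permeability, area=area, kp_ab=kp_ab)
    _check_nonnegative(conc_a=conc_a, conc_b=conc_b)
    return permeability * area * (conc_a - conc_b / kp_ab)


def mackie_meares_diffusivity(free_diffusivity: float, porosity: float) -> float:
    """Effective diffusivity in a porous membrane, D_eff = D*(e/(2-e))^2.

    The Mackie-Meares obstruction factor reduces the free aqueous diffusivity
    of the solute according to the membrane porosity ``e`` in (0, 1]; a fully
    porous membrane (e = 1) leaves the diffusivity unchanged.
    """
    _check_positive(free_diffusivity=free_diffusivity)
    if not math.isfinite(porosity) or not (0.0 < porosity <= 1.0):
        raise DomainError(f"porosity must lie in (0, 1], got {porosity!r}")
    f = porosity / (2.0 - porosity)
    return free_diffusivity * f * f


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CompoundProps:
    """Physicochemical record of the permeant, carried as metadata.

    pKa and vehicle pH are stored but not used by the transport model: no
    ionisation correction is part of the model.
    """
    molecular_weight: float     # g/mol
    log_p: float
    pka: float
    vehicle_ph: float

    def __post_init__(self) -> None:
        _check_positive(molecular_weight=self.molecular_weight)
        for name in ("log_p", "pka", "vehicle_ph"):
            if not math.isfinite(getattr(self, name)):
                raise DomainError(f"{name} must be finite")


#: Desoximetasone, the corticosteroid the reference formulations carry.
DESOXIMETASONE = CompoundProps(molecular_weight=376.5, log_p=2.35,
                               pka=13.44, vehicle_ph=7.4)


@dataclass(frozen=True)
class InterfaceSpec:
    """One interface of the flux network.

    Either both (delta, diff) film pairs are given and the permeability is the
    two-film series formula, or ``permeability_override`` supplies P directly
    (as the lipid/corneocyte rows of the skin parameter table do).
    """
    area: float                                 # m^2
    kp_ab: float = 1.0
    delta_a: float | None = None                # m
    diff_a: float | None = None                 # m^2/s
    delta_b: float | None = None
    diff_b: float | None = None
    permeability_override: float | None = None  # m/s

    def __post_init__(self) -> None:
        _check_positive(area=self.area, kp_ab=self.kp_ab)
        films = all(v is not None for v in
                    (self.delta_a, self.diff_a, self.delta_b, self.diff_b))
        if films == (self.permeability_override is not None):
            raise DomainError(
                "exactly one of the (delta, diff) film pairs or "
                "permeability_override must determine the permeability")
        if self.permeability_override is not None:
            _check_positive(permeability_override=self.permeability_override)

    @property
    def permeability(self) -> float:
        if self.permeability_override is not None:
            return self.permeability_override
        return series_permeability(self.delta_a, self.diff_a,
                                   self.delta_b, self.diff_b, self.kp_ab)

    def flux(self, conc_a: float, conc_b: float) -> float:
        return interface_flux(self.permeability, self.area,
                              conc_a, conc_b, self.kp_ab)


@dataclass
class CompartmentState:
    """A well-mixed compartment: volume (m^3) and concentration (kg/m^3)."""
    volume: float
    concentration: float = 0.0

    def __post_init__(self) -> None:
        _check_positive(volume=self.volume)
        _check_nonnegative(concentration=self.concentration)

    @property
    def amount(self) -> float:
        """Drug amount C*V in kg."""
        return self.concentration * self.volume


@dataclass(frozen=True)
class MembraneSpec:
    """Inert porous release membrane (IVRT barrier).

    ``free_diffusivity`` is the aqueous diffusivity of the solute; the
    effective in-membrane diffusivity applies the Mackie-Meares correction
    for ``porosity``.
    """
    thickness: float            # m
    porosity: float
    free_diffusivity: float     # m^2/s
    n_cells: int = 10

    def __post_init__(self) -> None:
        _check_positive(thickness=self.thickness,
                        free_diffusivity=self.free_diffusivity)
        if not (0.0 < self.porosity <= 1.0):
            raise DomainError(f"porosity must lie in (0, 1], got {self.porosity!r}")
        if self.n_cells < 1:
            raise DomainError("membrane needs at least one cell")

    @property
    def effective_diffusivity(self) -> float:
        return mackie_meares_diffusivity(self.free_diffusivity, self.porosity)


@dataclass(frozen=True)
class SamplingSchedule:
    """Receptor sampling/replenishment protocol.

    At each time an aliquot ``sample_volume`` is withdrawn and replaced by the
    same volume of fresh medium at ``replacement_concentration`` (0 for PBS),
    so the receptor volume is constant while its concentration drops.
    """
    times: tuple[float, ...]                    # s, strictly increasing
    sample_volume: float = 400 * 1e-9           # 400 uL in m^3
    replacement_concentration: float = 0.0      # kg/m^3

    def __post_init__(self) -> None:
        _check_nonnegative(sample_volume=self.sample_volume,
                           replacement_concentration=self.replacement_concentration)
        ts = tuple(float(t) for t in self.times)
        if any(t < 0 for t in ts):
            raise DomainError("sampling times must be non-negative")
        if any(b <= a for a, b in zip(ts, ts[1:])):
            raise DomainError("sampling times must be strictly increasing")
        object.__setattr__(self, "times", ts)


@dataclass(frozen=True)
class FranzCellConfig:
    """Geometry and protocol of the virtual Franz diffusion cell."""
    diffusion_area: float = 0.64e-4             # m^2  (0.64 cm^2)
    receptor_volume: float = 4.7e-6             # m^3  (4.7 mL)
    duration: float = 36 * 3600.0               # s
    sampling: SamplingSchedule = field(
        default_factory=lambda: SamplingSchedule(times=()))

    def __post_init__(self) -> None:
        _check_positive(diffusion_area=self.diffusion_area,
                        receptor_volume=self.receptor_volume,
                        duration=self.duration)
        if self.sampling.sample_volume >= self.receptor_volume:
            raise DomainError("sample_volume must be smaller than the receptor volume")
        if any(t > self.duration for t in self.sampling.times):
            raise DomainError("sampling times must lie within [0, duration]")


def geometric_widths(length: float, n: int, ratio: float = 1.2,
                     refine: str = "start") -> "list[float]":
    """1-D finite-volume cell widths over ``length``.

    ``refine='start'`` places the thinnest cell at index 0 (widths grow by
    ``ratio``); ``'both'`` refines symmetrically toward both ends (n even).
    """
    _check_positive(length=length)
    if n < 1:
        raise DomainError("need at least one cell")
    if n == 1 or ratio == 1.0:
        return [length / n] * n
    if refine == "start":
        w0 = length * (ratio - 1.0) / (ratio ** n - 1.0)
        return [w0 * ratio ** i for i in range(n)]
    if refine == "both":
        if n % 2:
            raise DomainError("two-sided refinement needs an even cell count")
        half = geometric_widths(length / 2.0, n // 2, ratio, refine="start")
        return half + half[::-1]
    raise DomainError(f"unknown refinement mode {refine!r}")


def sampling_times_hours(hours: Sequence[float]) -> tuple[float, ...]:
    return tuple(float(h) * 3600.0 for h in hours)
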