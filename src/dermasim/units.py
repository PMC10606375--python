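"""Unit constants and boundary conversions.

All internal state is strict SI (m, s, kg, kg/m^3).  Franz-cell practice mixes
micrograms, millilitres, square centimetres and hours; these constants convert
at the user-facing boundary only.
"""

from __future__ import annotations

# lengths
M = 1.0
CM = 1e-2
MM = 1e-3
UM = 1e-6
NM = 1e-9

# areas / volumes
CM2 = 1e-4          # m^2
ML = 1e-6           # m^3
UL = 1e-9           # m^3

# masses
KG = 1.0
G = 1e-3
MG = 1e-6
UG = 1e-9

# time
S = 1.0
MIN = 60.0
HOUR = 3600.0

# concentration: 1 mg/mL == 1 kg/m^3; 1 ug/mL == 1e-3 kg/m^3
MG_PER_ML = 1.0
UG_PER_ML = 1e-3


def kg_to_ug(x: float) -> float:
    return x / UG


def ug_to_kg(x: float) -> float:
    return x * UG


def api_dose_ug(formulation_mass_mg: float, strength_fraction: float) -> float:
    """Drug (API) content of an applied dose of semisolid formulation.

    Parameters
    ----------
    formulation_mass_mg:
        Mass of formulation applied to the donor chamber, in mg.
    strength_fraction:
        Label strength as a w/w fraction (0.25 % -> 0.0025).

    Returns
    -------
    API mass in micrograms.  500 mg of a 0.25 % w/w product carries 1250 ug.
    """
    if formulation_mass_mg < 0 or not (0 <= strength_fraction <= 1):
        raise ValueError("formulation mass must be >= 0 and strength a fraction in [0, 1]")
    return formulation_mass_mg * 1e3 * strength_fraction
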