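"""Heat-transfer calculators for interpreting animal surface temperatures.

Three standard equations frame how a homeotherm exchanges heat with a cold
environment:

* forced convection ``Q = h_c * A * dT``, the heat carried away from a body
  of surface area ``A`` by moving air when its surface is ``dT`` warmer (or
  colder) than the air;
* the surface heat-transfer coefficient ``h_c = c * V**k1 / D**k2``, which
  captures how wind speed ``V`` and the characteristic dimension ``D`` of the
  organism (through its boundary layer, i.e. the hair coat) set the convective
  coupling — the exponents bundle thermal conductivity/capacity/expansion
  effects and are organism-specific, so they are user inputs here;
* net radiation ``Q_n = A * eps * sigma * (T_o**4 - T_e**4)``, the
  Stefan–Boltzmann radiative balance between an organism at ``T_o`` and an
  environment at ``T_e`` (both in kelvin).

These are standalone calculators: they are deliberately not coupled into the
regression pipeline, which treats them as interpretive context for the
temperature differences it models.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.constants import Stefan_Boltzmann as STEFAN_BOLTZMANN

#: Emissivity of cattle hide as configured on the infrared thermometer used
#: for the surface-temperature measurements this package models.
DEFAULT_EMISSIVITY = 0.93


@dataclass(frozen=True)
class ConvectionSpec:
    """Symbols of the forced-convection model.

    Attributes
    ----------
    h_c : float
        Surface heat-transfer coefficient, W m^-2 K^-1.
    area : float
        Surface area of the body, m^2 (> 0).
    delta_t : float
        Surface-minus-environment temperature difference, K (signed).
    wind_speed : float
        V, m s^-1 (>= 0).
    dimension : float
        Characteristic dimension D of the organism, m (> 0).
    k1, k2 : float
        Dimensionless exponents of the h_c scaling law.
    c : float
        Proportionality constant standing in for the unspecified function f.
    """

    h_c: float = 1.0
    area: float = 1.0
    delta_t: float = 0.0
    wind_speed: float = 0.0
    dimension: float = 1.0
    k1: float = 1.0
    k2: float = 1.0
    c: float = 1.0


@dataclass(frozen=True)
class RadiationSpec:
    """Symbols of the net-radiation (Stefan–Boltzmann) balance."""

    area: float = 1.0
    emissivity: float = DEFAULT_EMISSIVITY
    t_organism: float = 273.15
    t_environment: float = 273.15

    def __post_init__(self) -> None:
        if not 0.0 <= self.emissivity <= 1.0:
            raise ValueError("emissivity must lie in [0, 1]")
        if self.t_organism <= 0 or self.t_environment <= 0:
            raise ValueError("temperatures must be absolute (kelvin, > 0)")


def celsius_to_kelvin(celsius: float) -> float:
    """Convert a Celsius temperature to kelvin."""
    kelvin = celsius + 273.15
    if kelvin <= 0:
        raise ValueError(f"{celsius} degC is below absolute zero")
    return kelvin


def forced_convection(h_c: float, area: float, delta_t: float) -> float:
    """Convective heat flux Q = h_c * A * dT (W).

    The sign of Q follows the sign of ``delta_t``: a surface warmer than the
    surrounding air loses heat (Q > 0 under the sign convention used here).
    """
    if area <= 0:
        raise ValueError("surface area must be positive")
    return h_c * area * delta_t


def surface_heat_transfer_coefficient(
    wind_speed: float,
    dimension: float,
    k1: float = 1.0,
    k2: float = 1.0,
    c: float = 1.0,
) -> float:
    """Surface heat-transfer coefficient h_c = c * V**k1 / D**k2.

    The functional form experimentalists fit is organism-specific and rarely
    determined; this calculator exposes the scaling law with the
    proportionality constant ``c`` and exponents ``k1``/``k2`` as explicit
    user inputs rather than asserting defaults as biological truth.
    """
    if dimension <= 0:
        raise ValueError("characteristic dimension D must be positive")
    if wind_speed < 0:
        raise ValueError("wind speed must be non-negative")
    return c * wind_speed**k1 / dimension**k2


def net_radiation(
    area: float,
    emissivity: float,
    t_organism: float,
    t_environment: float,
) -> float:
    """Net radiative flux Q_n = A * eps * sigma * (T_o^4 - T_e^4) (W).

    Temperatures must be supplied in kelvin: the fourth-power law is
    meaningless on the Celsius scale. Use :func:`celsius_to_kelvin`.
    """
    if t_organism <= 0 or t_environment <= 0:
        raise ValueError("temperatures must be in kelvin (> 0)")
    if not 0.0 <= emissivity <= 1.0:
        raise ValueError("emissivity must lie in [0, 1]")
    if area < 0:
        raise ValueError("area must be non-negative")
    return area * emissivity * STEFAN_BOLTZMANN * (t_organism**4 - t_environment**4)
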