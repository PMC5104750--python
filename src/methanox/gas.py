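"""Headspace-equilibration back-calculation of dissolved methane.

Dissolved CH₄ is measured by introducing an N₂ headspace into a filled serum
bottle, letting the phases equilibrate, and quantifying CH₄ in the gas phase
by GC.  The original dissolved concentration is then recovered from the gas
measurement using a Bunsen solubility coefficient β(T, S): at equilibrium

    n_total = n_gas + n_aq
    n_gas   = x·P·V_gas / (R·T)            (ideal gas)
    n_aq    = β·x·P / V_m,STP · V_water    (Bunsen definition)

where x is the headspace CH₄ mole fraction, P the total pressure and
V_m,STP = 22.414 L mol⁻¹ the molar gas volume at standard conditions that
enters the Bunsen definition (volume of gas at STP absorbed per volume of
liquid at 1 atm partial pressure).

The default coefficients are the ln-β fit in temperature and salinity for
methane from the oceanographic solubility literature (valid roughly −2 to
30 °C, S 0–40); an ideal-gas/Henry fallback with a user-supplied constant is
available through a custom :class:`SolubilityModel`.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

__all__ = [
    "SolubilityModel",
    "HeadspaceSample",
    "CH4_BUNSEN",
    "SolubilityRangeError",
    "bunsen_coefficient",
    "headspace_to_dissolved",
    "partition_dissolved",
    "atmospheric_equilibrium",
]

R_L_ATM = 0.082057366  # L atm mol^-1 K^-1
V_MOLAR_STP = 22.414  # L mol^-1, molar volume entering the Bunsen definition


class SolubilityRangeError(ValueError):
    """Temperature or salinity outside the validity range of the fit."""


@dataclass(frozen=True)
class SolubilityModel:
    """Bunsen-coefficient fit ln β = A1 + A2(100/T) + A3 ln(T/100)
    + S·[B1 + B2(T/100) + B3(T/100)²], with T in kelvin and S in ‰."""

    name: str
    a1: float
    a2: float
    a3: float
    b1: float
    b2: float
    b3: float
    t_range_c: tuple[float, float] = (-2.0, 30.0)
    s_range: tuple[float, float] = (0.0, 40.0)

    def bunsen(self, temperature_c: float, salinity: float = 0.0) -> float:
        t_k = temperature_c + 273.15
        t100 = t_k / 100.0
        ln_beta = (
            self.a1
            + self.a2 * (100.0 / t_k)
            + self.a3 * math.log(t100)
            + salinity * (self.b1 + self.b2 * t100 + self.b3 * t100 * t100)
        )
        return math.exp(ln_beta)


#: CH₄ Bunsen coefficient fit (atmospheric-equilibrium solubility family),
#: versioned so revised constants can be swapped in without touching callers.
CH4_BUNSEN = SolubilityModel(
    name="ch4-bunsen-v1",
    a1=-67.1962,
    a2=99.1624,
    a3=27.9015,
    b1=-0.072909,
    b2=0.041674,
    b3=-0.0064603,
)


@dataclass(frozen=True)
class HeadspaceSample:
    """One headspace-equilibrated bottle.

    Default geometry is a 120 mL serum bottle with a 20 mL N₂ headspace over
    100 mL of sample water; equilibration is assumed complete and isothermal
    at the stated (lab) temperature.
    """

    x_ch4: float  # headspace mole fraction after equilibration
    v_water_ml: float = 100.0
    v_gas_ml: float = 20.0
    temperature_c: float = 20.0
    salinity: float = 0.0
    pressure_atm: float = 1.0

    def __post_init__(self) -> None:
        if self.v_water_ml <= 0 or self.v_gas_ml <= 0:
            raise ValueError("phase volumes must be positive")
        if not 0.0 <= self.x_ch4 <= 1.0:
            raise ValueError(f"mole fraction must be in [0, 1], got {self.x_ch4}")


def _check_range(model: SolubilityModel, temperature_c: float, salinity: float,
                 strict: bool) -> None:
    t_lo, t_hi = model.t_range_c
    s_lo, s_hi = model.s_range
    if not (t_lo <= temperature_c <= t_hi and s_lo <= salinity <= s_hi):
        msg = (
            f"(T={temperature_c} degC, S={salinity}) outside the validity range "
            f"of {model.name} (T {t_lo}..{t_hi}, S {s_lo}..{s_hi})"
        )
        if strict:
            raise SolubilityRangeError(msg)
        warnings.warn(msg, stacklevel=3)


def bunsen_coefficient(
    model: SolubilityModel,
    temperature_c: float,
    salinity: float = 0.0,
    strict_range: bool = True,
) -> float:
    """Evaluate the Bunsen solubility coefficient β(T, S) (dimensionless).

    β decreases with temperature (warming degasses) and with salinity
    (salting-out).  Outside the fit's validity range an error is raised, or
    a warning if ``strict_range`` is False.
    """
    _check_range(model, temperature_c, salinity, strict_range)
    return model.bunsen(temperature_c, salinity)


def headspace_to_dissolved(
    sample: HeadspaceSample, model: SolubilityModel = CH4_BUNSEN
) -> float:
    """Original dissolved CH₄ concentration (µM) before headspace creation.

    Sums the moles found in the equilibrated gas phase and those remaining
    dissolved, and divides by the water volume.  Linear in the measured mole
    fraction; exact phase-partitioning closure is guaranteed by construction
    (see :func:`partition_dissolved`).
    """
    beta = bunsen_coefficient(model, sample.temperature_c, sample.salinity)
    p_ch4 = sample.x_ch4 * sample.pressure_atm
    t_k = sample.temperature_c + 273.15
    v_gas_l = sample.v_gas_ml / 1000.0
    v_water_l = sample.v_water_ml / 1000.0
    n_gas = p_ch4 * v_gas_l / (R_L_ATM * t_k)
    c_aq = beta * p_ch4 / V_MOLAR_STP  # mol per L water
    n_total = n_gas + c_aq * v_water_l
    return n_total / v_water_l * 1e6  # mol/L -> µM


def partition_dissolved(
    c0_uM: float, sample_geometry: HeadspaceSample, model: SolubilityModel = CH4_BUNSEN
) -> float:
    """Forward model: equilibrium headspace mole fraction for a known C₀.

    Distributes ``c0_uM`` (µM in the water phase before equilibration) over
    the two phases of ``sample_geometry`` and returns the headspace CH₄ mole
    fraction.  Used to build synthetic GC readings and as the closure
    counterpart of :func:`headspace_to_dissolved`.
    """
    beta = bunsen_coefficient(model, sample_geometry.temperature_c,
                              sample_geometry.salinity)
    t_k = sample_geometry.temperature_c + 273.15
    v_gas_l = sample_geometry.v_gas_ml / 1000.0
    v_water_l = sample_geometry.v_water_ml / 1000.0
    n_total = c0_uM * 1e-6 * v_water_l
    # n_total = p·[V_g/(RT) + beta·V_w/Vm]; x = p / P_total
    p = n_total / (v_gas_l / (R_L_ATM * t_k) + beta * v_water_l / V_MOLAR_STP)
    return p / sample_geometry.pressure_atm


def atmospheric_equilibrium(
    model: SolubilityModel,
    temperature_c: float,
    salinity: float = 0.0,
    x_atm: float = 1.9e-6,
    pressure_atm: float = 1.0,
) -> float:
    """Dissolved CH₄ (nM) in equilibrium with an atmosphere of mole fraction
    ``x_atm`` (default ~1.9 ppmv).  This is the infinite-headspace limit of
    the partitioning model."""
    beta = bunsen_coefficient(model, temperature_c, salinity)
    c_mol_l = beta * x_atm * pressure_atm / V_MOLAR_STP
    return c_mol_l * 1e9
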