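"""Turbulent diffusive fluxes and the electron-equivalent redox budget.

Vertical solute transport across a stratified water column is modelled as
turbulent diffusion, J = −Kz·∂C/∂z, with Kz a vertical turbulent dispersion
coefficient.  Per-species fluxes across the methane-oxidation zone are
converted to electron equivalents using the electron accepting/donating
capacity of an assumed half-reaction, and summed into an acceptor/donor
budget whose imbalance (the electron-acceptor deficit) measures how much
reducing power is not accounted for by the measured oxidant fluxes.

Sign convention: depth increases downward and fluxes are positive downward,
so an analyte increasing with depth (supplied from below, e.g. CH₄) carries a
negative, upward flux, while one decreasing with depth (supplied from above,
e.g. O₂) carries a positive, downward flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .profiles import MissingAnalyteError, Profile

__all__ = [
    "ProfileGradient",
    "DispersionCoefficient",
    "ElectronCapacity",
    "ElectronCapacityTable",
    "ElectronFlux",
    "ElectronBudget",
    "MissingCapacityError",
    "IncompleteBudgetError",
    "CM2_S_TO_M2_D",
    "DEFAULT_CAPACITIES",
    "HALF_REACTIONS",
    "steepest_gradient",
    "diffusive_flux",
    "electron_flux",
    "budget",
    "oxidant_ratio",
    "report_round",
]

#: 1 cm² s⁻¹ expressed in m² d⁻¹ (1e-4 m² per cm² × 86400 s per day).
CM2_S_TO_M2_D = 1e-4 * 86400.0  # = 8.64


class MissingCapacityError(KeyError):
    """Species has no entry in the electron-capacity table."""


class IncompleteBudgetError(ValueError):
    """Budget needs at least one acceptor and one donor flux."""


class InsufficientDataError(ValueError):
    """Too few finite points for a gradient fit."""


@dataclass(frozen=True)
class ProfileGradient:
    """OLS concentration gradient (µM m⁻¹) over a depth window."""

    analyte: str
    slope: float
    stderr: float
    depth_window: tuple[float, float]
    n_points: int
    r_squared: float

    def __post_init__(self) -> None:
        if self.depth_window[0] >= self.depth_window[1]:
            raise ValueError("depth window top must be above bottom")
        if self.n_points < 2:
            raise ValueError("gradient needs >= 2 points")


@dataclass(frozen=True)
class DispersionCoefficient:
    """Vertical turbulent dispersion coefficient Kz in cm² s⁻¹."""

    kz_cm2_s: float = 4e-3
    source: str = "low-mixing default"

    def __post_init__(self) -> None:
        if self.kz_cm2_s <= 0:
            raise ValueError("Kz must be positive")

    @property
    def kz_m2_d(self) -> float:
        return self.kz_cm2_s * CM2_S_TO_M2_D


@dataclass(frozen=True)
class ElectronCapacity:
    """Electrons transferred per mole of species in its assumed half-reaction."""

    species: str
    half_reaction: str
    electrons: int
    role: str  # "acceptor" or "donor"

    def __post_init__(self) -> None:
        if self.electrons < 1:
            raise ValueError("electron capacity must be >= 1")
        if self.role not in ("acceptor", "donor"):
            raise ValueError(f"role must be acceptor or donor, got {self.role!r}")


#: Electrons per mole for the half-reactions used anywhere in the package.
#: The stoichiometric-ratio context uses NO3- -> NO2- (2 e-), whereas the
#: column budget assumes full denitrification NO3- -> N2 (5 e-).
HALF_REACTIONS: Mapping[str, int] = {
    "O2 -> H2O": 4,
    "CH4 -> CO2": 8,
    "NO3- -> N2": 5,
    "NO3- -> NO2-": 2,
    "NO2- -> N2": 3,
    "SO42- -> H2S": 8,
    "NH4+ -> NO3-": 8,
    "Fe2+ -> Fe(III)": 1,
    "Mn2+ -> Mn(IV)": 2,
    "H2S -> SO42-": 8,
}

DEFAULT_CAPACITIES: tuple[ElectronCapacity, ...] = (
    ElectronCapacity("O2", "O2 -> H2O", 4, "acceptor"),
    ElectronCapacity("NO3-", "NO3- -> N2", 5, "acceptor"),
    ElectronCapacity("NO2-", "NO2- -> N2", 3, "acceptor"),
    ElectronCapacity("SO42-", "SO42- -> H2S", 8, "acceptor"),
    ElectronCapacity("CH4", "CH4 -> CO2", 8, "donor"),
    ElectronCapacity("NH4+", "NH4+ -> NO3-", 8, "donor"),
    ElectronCapacity("Fe2+", "Fe2+ -> Fe(III)", 1, "donor"),
    ElectronCapacity("Mn2+", "Mn2+ -> Mn(IV)", 2, "donor"),
    ElectronCapacity("H2S", "H2S -> SO42-", 8, "donor"),
)


@dataclass(frozen=True)
class ElectronCapacityTable:
    """Species → electron-capacity mapping, one default entry per species.

    The defaults are overridable (``with_override``) and every downstream
    report names the half-reaction actually used, since different communities
    terminate e.g. nitrate reduction at different products.
    """

    entries: tuple[ElectronCapacity, ...] = DEFAULT_CAPACITIES

    def __post_init__(self) -> None:
        species = [e.species for e in self.entries]
        if len(species) != len(set(species)):
            raise ValueError("each species must have exactly one entry")

    def __getitem__(self, species: str) -> ElectronCapacity:
        for entry in self.entries:
            if entry.species == species:
                return entry
        raise MissingCapacityError(species)

    def __contains__(self, species: str) -> bool:
        return any(e.species == species for e in self.entries)

    def with_override(self, capacity: ElectronCapacity) -> "ElectronCapacityTable":
        others = tuple(e for e in self.entries if e.species != capacity.species)
        return ElectronCapacityTable(others + (capacity,))


@dataclass(frozen=True)
class ElectronFlux:
    """One species' electron-equivalent flux (mmol e⁻ m⁻² d⁻¹, signed)."""

    species: str
    value: float
    sigma: float
    role: str
    half_reaction: str = ""
    molar_flux: float = float("nan")  # mmol m^-2 d^-1, before capacity scaling


@dataclass(frozen=True)
class ElectronBudget:
    """Acceptor/donor electron-flux budget with quadrature uncertainties.

    ``acceptor_sum``/``donor_sum``/``deficit`` are unrounded; the matching
    ``reported_*`` attributes apply the report rounding policy (one decimal
    at |v| ≥ 0.1, two below), and the reported deficit is the difference of
    the *rounded* sums so that the printed table stays internally consistent.
    """

    fluxes: tuple[ElectronFlux, ...]
    acceptor_sum: float
    acceptor_sigma: float
    donor_sum: float
    donor_sigma: float
    deficit: float
    deficit_sigma: float

    @property
    def reported_acceptor_sum(self) -> float:
        return report_round(self.acceptor_sum)

    @property
    def reported_donor_sum(self) -> float:
        return report_round(self.donor_sum)

    @property
    def reported_deficit(self) -> float:
        return report_round(
            abs(self.reported_donor_sum) - self.reported_acceptor_sum
        )

    def to_frame(self):
        """Delimited-table form: species, role, half-reaction, e⁻ flux ± σ."""
        import pandas as pd

        rows = [
            {
                "species": f.species,
                "role": f.role,
                "half_reaction": f.half_reaction,
                "e_flux_mmol_m2_d": report_round(f.value),
                "sigma": report_round(f.sigma),
            }
            for f in self.fluxes
        ]
        rows.append(
            {
                "species": "Sum (acceptors)",
                "role": "acceptor",
                "half_reaction": "",
                "e_flux_mmol_m2_d": self.reported_acceptor_sum,
                "sigma": report_round(self.acceptor_sigma),
            }
        )
        rows.append(
            {
                "species": "Sum (donors)",
                "role": "donor",
                "half_reaction": "",
                "e_flux_mmol_m2_d": self.reported_donor_sum,
                "sigma": report_round(self.donor_sigma),
            }
        )
        rows.append(
            {
                "species": "Deficit",
                "role": "",
                "half_reaction": "",
                "e_flux_mmol_m2_d": self.reported_deficit,
                "sigma": report_round(self.deficit_sigma),
            }
        )
        return pd.DataFrame(rows)


def report_round(value: float) -> float:
    """One decimal for |v| ≥ 0.1, two decimals below (mixed table precision)."""
    return round(value, 1) if abs(value) >= 0.1 else round(value, 2)


def steepest_gradient(
    profile: Profile, analyte: str, window_points: int = 3
) -> ProfileGradient:
    """Steepest-slope OLS gradient of one analyte.

    Fits a straight line in every contiguous depth window of
    ``window_points`` samples and returns the fit with the largest absolute
    slope; ties go to the shallower window.
    """
    depths, values = profile.analyte(analyte)
    n = len(depths)
    if n < window_points:
        raise InsufficientDataError(
            f"{analyte}: {n} finite points < window of {window_points}"
        )
    if window_points < 2:
        raise ValueError("window must span at least 2 points")
    best: ProfileGradient | None = None
    for start in range(n - window_points + 1):
        z = depths[start : start + window_points]
        c = values[start : start + window_points]
        fit = stats.linregress(z, c)
        candidate = ProfileGradient(
            analyte=analyte,
            slope=float(fit.slope),
            stderr=float(fit.stderr) if math.isfinite(fit.stderr) else 0.0,
            depth_window=(float(z[0]), float(z[-1])),
            n_points=window_points,
            r_squared=float(fit.rvalue**2) if math.isfinite(fit.rvalue) else 0.0,
        )
        if best is None or abs(candidate.slope) > abs(best.slope):
            best = candidate
    assert best is not None
    return best


def diffusive_flux(
    gradient: ProfileGradient, kz: DispersionCoefficient
) -> tuple[float, float]:
    """Fick flux J = −Kz·∂C/∂z in mmol m⁻² d⁻¹ with its uncertainty.

    The gradient is in µM m⁻¹ ≡ mmol m⁻⁴ and Kz is converted to m² d⁻¹, so
    the product is directly mmol m⁻² d⁻¹.  A concentration increasing with
    depth yields a negative (upward) flux.
    """
    j = -kz.kz_m2_d * gradient.slope
    sigma = kz.kz_m2_d * gradient.stderr
    return j, sigma


def electron_flux(
    molar_flux: float,
    table: ElectronCapacityTable,
    species: str,
    sigma: float = 0.0,
) -> ElectronFlux:
    """Scale a molar flux by the species' electron capacity."""
    entry = table[species]
    return ElectronFlux(
        species=species,
        value=molar_flux * entry.electrons,
        sigma=abs(sigma) * entry.electrons,
        role=entry.role,
        half_reaction=entry.half_reaction,
        molar_flux=molar_flux,
    )


def budget(e_fluxes: Sequence[ElectronFlux]) -> ElectronBudget:
    """Assemble the acceptor/donor electron budget.

    Sums per role, propagates the per-species uncertainties in quadrature
    (species fluxes are treated as independent), and computes the
    electron-acceptor deficit |Σ donors| − Σ acceptors.  Permutation
    invariant and additive under splitting a species' flux in two.
    """
    acceptors = [f for f in e_fluxes if f.role == "acceptor"]
    donors = [f for f in e_fluxes if f.role == "donor"]
    if not acceptors or not donors:
        raise IncompleteBudgetError(
            "budget requires at least one acceptor and one donor flux"
        )
    # fsum keeps the sums exact, hence permutation invariant
    acc_sum = math.fsum(f.value for f in acceptors)
    don_sum = math.fsum(f.value for f in donors)
    acc_sigma = math.sqrt(math.fsum(f.sigma**2 for f in acceptors))
    don_sigma = math.sqrt(math.fsum(f.sigma**2 for f in donors))
    return ElectronBudget(
        fluxes=tuple(e_fluxes),
        acceptor_sum=acc_sum,
        acceptor_sigma=acc_sigma,
        donor_sum=don_sum,
        donor_sigma=don_sigma,
        deficit=abs(don_sum) - acc_sum,
        deficit_sigma=math.sqrt(acc_sigma**2 + don_sigma**2),
    )


def oxidant_ratio(
    oxidant_half_reaction: str,
    donor_half_reaction: str = "CH4 -> CO2",
    half_reactions: Mapping[str, int] = HALF_REACTIONS,
) -> float:
    """Moles of oxidant required per mole of donor, from half-reaction
    electron counts: ratio = e⁻ donated / e⁻ accepted.

    With CH₄ → CO₂ (8 e⁻): nitrate reduced only to nitrite (2 e⁻) gives 4:1,
    nitrite to N₂ (3 e⁻) gives 8:3, and O₂ gives the familiar 2:1.
    """
    try:
        donated = half_reactions[donor_half_reaction]
        accepted = half_reactions[oxidant_half_reaction]
    except KeyError as exc:
        raise MissingCapacityError(str(exc)) from exc
    if donated == 0 or accepted == 0:
        raise ValueError("half-reactions must transfer at least one electron")
    return donated / accepted
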