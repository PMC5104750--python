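"""Gradient selection, Fick fluxes, and the electron budget."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from methanox.flux import (
    DispersionCoefficient,
    ElectronCapacity,
    ElectronCapacityTable,
    ElectronFlux,
    IncompleteBudgetError,
    MissingCapacityError,
    budget,
    diffusive_flux,
    electron_flux,
    oxidant_ratio,
    report_round,
    steepest_gradient,
)
from methanox.profiles import Profile

from conftest import make_profile


class TestSteepestGradient:
    def test_linear_profile_any_window(self):
        depths = np.arange(0.0, 10.0, 0.5)
        prof = make_profile(depth_m=depths, x=3.0 * depths + 1.0)
        for w in (3, 5, 8):
            g = steepest_gradient(prof, "x", w)
            assert g.slope == pytest.approx(3.0, rel=1e-12)
            assert g.r_squared == pytest.approx(1.0)

    def test_constant_profile_zero_slope(self):
        prof = make_profile(depth_m=np.arange(10.0), x=np.full(10, 7.0))
        assert steepest_gradient(prof, "x").slope == pytest.approx(0.0, abs=1e-12)

    def test_piecewise_steep_segment_found(self):
        depths = np.arange(0.0, 21.0, 0.5)
        values = np.interp(depths, [0, 13, 15, 21], [260, 250, 2, 0])
        prof = make_profile(depth_m=depths, o2=values)
        g = steepest_gradient(prof, "o2", 3)
        assert 13.0 <= g.depth_window[0] and g.depth_window[1] <= 15.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        depths = np.sort(rng.uniform(0, 20, 40))
        values = np.cumsum(rng.normal(0, 5, 40))
        prof = make_profile(depth_m=depths, x=values)
        for w in (2, 3, 6):
            g = steepest_gradient(prof, "x", w)
            # independent exhaustive search over every contiguous window
            best_slope, best_start = 0.0, None
            for start in range(len(depths) - w + 1):
                slope = np.polyfit(
                    depths[start : start + w], values[start : start + w], 1
                )[0]
                if best_start is None or abs(slope) > abs(best_slope):
                    best_slope, best_start = slope, start
            assert g.slope == pytest.approx(best_slope, rel=1e-9)
            assert g.depth_window[0] == pytest.approx(depths[best_start])

    def test_tie_broken_toward_shallow(self):
        # two symmetric ramps with identical |slope|
        depths = np.arange(0.0, 9.0)
        values = np.array([0, 1, 2, 2, 2, 2, 2, 1, 0], float)
        g = steepest_gradient(make_profile(depth_m=depths, x=values), "x", 3)
        assert g.depth_window == (0.0, 2.0)


class TestDiffusiveFlux:
    KZ = DispersionCoefficient(4e-3)

    def grad(self, slope, stderr=0.0):
        from methanox.flux import ProfileGradient

        return ProfileGradient("x", slope, stderr, (12.0, 16.0), 3, 1.0)

    def test_kz_unit_conversion(self):
        assert self.KZ.kz_m2_d == pytest.approx(0.03456, rel=1e-12)

    def test_zero_slope_zero_flux(self):
        assert diffusive_flux(self.grad(0.0), self.KZ)[0] == 0.0

    def test_linear_in_kz(self):
        j1, _ = diffusive_flux(self.grad(-100.0), DispersionCoefficient(4e-3))
        j2, _ = diffusive_flux(self.grad(-100.0), DispersionCoefficient(8e-3))
        assert j2 == pytest.approx(2 * j1, rel=1e-12)

    def test_hand_converted_oxygen_scale_flux(self):
        # -289.35 µM/m × 0.03456 m²/d = +10.0 mmol m⁻² d⁻¹ (downward)
        j, sigma = diffusive_flux(self.grad(-289.35, stderr=10.0), self.KZ)
        assert j == pytest.approx(10.0, abs=1e-4)
        assert sigma == pytest.approx(10.0 * 0.03456, rel=1e-12)

    def test_upward_flux_for_bottom_sourced_solute(self):
        j, _ = diffusive_flux(self.grad(+250.0), self.KZ)
        assert j < 0


class TestElectronFlux:
    TABLE = ElectronCapacityTable()

    def test_methane_eight_electrons(self):
        ef = electron_flux(-1.3875, self.TABLE, "CH4", sigma=0.25)
        assert ef.value == pytest.approx(-11.1, abs=1e-9)
        assert ef.sigma == pytest.approx(2.0, rel=1e-9)
        assert ef.role == "donor"
        assert ef.half_reaction == "CH4 -> CO2"

    def test_zero_flux(self):
        assert electron_flux(0.0, self.TABLE, "O2").value == 0.0

    def test_single_electron_species_unchanged(self):
        assert electron_flux(-0.03, self.TABLE, "Fe2+").value == pytest.approx(-0.03)

    def test_unknown_species(self):
        with pytest.raises(MissingCapacityError):
            electron_flux(1.0, self.TABLE, "ClO4-")

    def test_override_replaces_entry(self):
        table = self.TABLE.with_override(
            ElectronCapacity("NO3-", "NO3- -> NO2-", 2, "acceptor")
        )
        assert table["NO3-"].electrons == 2
        assert len([e for e in table.entries if e.species == "NO3-"]) == 1


def table2_fluxes():
    """The printed per-species electron fluxes of the study's budget table."""
    return [
        ElectronFlux("O2", 7.3, 0.03, "acceptor", "O2 -> H2O"),
        ElectronFlux("NO3-", 0.15, 0.02, "acceptor", "NO3- -> N2"),
        ElectronFlux("SO42-", 0.01, 0.09, "acceptor", "SO42- -> H2S"),
        ElectronFlux("CH4", -11.1, 2.0, "donor", "CH4 -> CO2"),
        ElectronFlux("Fe2+", -0.03, 0.01, "donor", "Fe2+ -> Fe(III)"),
        ElectronFlux("NH4+", -1.7, 0.45, "donor", "NH4+ -> NO3-"),
    ]


class TestBudget:
    def test_sums_and_deficit(self):
        b = budget(table2_fluxes())
        assert b.acceptor_sum == pytest.approx(7.46, abs=1e-12)
        assert b.donor_sum == pytest.approx(-12.83, abs=1e-12)
        assert b.deficit == pytest.approx(12.83 - 7.46, abs=1e-12)

    def test_quadrature_propagation(self):
        b = budget(table2_fluxes())
        assert b.acceptor_sigma == pytest.approx(
            math.sqrt(0.03**2 + 0.02**2 + 0.09**2), rel=1e-12
        )
        assert b.donor_sigma == pytest.approx(
            math.sqrt(2.0**2 + 0.01**2 + 0.45**2), rel=1e-12
        )

    def test_permutation_invariance(self):
        fluxes = table2_fluxes()
        b0 = budget(fluxes)
        b1 = budget(list(reversed(fluxes)))
        assert b0.acceptor_sum == b1.acceptor_sum
        assert b0.deficit == b1.deficit

    def test_splitting_a_flux_leaves_sums_unchanged(self):
        fluxes = table2_fluxes()
        split = [f for f in fluxes if f.species != "O2"] + [
            ElectronFlux("O2a", 4.0, 0.0, "acceptor", "O2 -> H2O"),
            ElectronFlux("O2b", 3.3, 0.03, "acceptor", "O2 -> H2O"),
        ]
        assert budget(split).acceptor_sum == pytest.approx(
            budget(fluxes).acceptor_sum, rel=1e-12
        )

    def test_missing_role_group_rejected(self):
        with pytest.raises(IncompleteBudgetError):
            budget([f for f in table2_fluxes() if f.role == "acceptor"])

    def test_quadrature_matches_monte_carlo(self):
        """Analytic sum uncertainty vs 10⁵-draw Monte-Carlo propagation."""
        rng = np.random.default_rng(123)
        fluxes = table2_fluxes()
        b = budget(fluxes)
        draws = np.zeros(100_000)
        for f in fluxes:
            if f.role == "acceptor":
                draws += rng.normal(f.value, f.sigma, size=draws.shape)
        mc_sigma = draws.std(ddof=1)
        assert abs(mc_sigma - b.acceptor_sigma) / b.acceptor_sigma <= 0.02

    def test_report_rounding_policy(self):
        assert report_round(7.46) == 7.5
        assert report_round(-12.83) == -12.8
        assert report_round(0.014) == 0.01
        assert report_round(-0.031) == -0.03

    def test_frame_has_summary_rows(self):
        frame = budget(table2_fluxes()).to_frame()
        assert list(frame["species"].tail(3)) == [
            "Sum (acceptors)", "Sum (donors)", "Deficit",
        ]


class TestOxidantRatio:
    @pytest.mark.parametrize(
        "oxidant, expected",
        [
            ("NO3- -> NO2-", 4.0),
            ("NO2- -> N2", 8.0 / 3.0),
            ("O2 -> H2O", 2.0),
        ],
    )
    def test_methane_coupled_ratios(self, oxidant, expected):
        assert oxidant_ratio(oxidant) == pytest.approx(expected, rel=1e-12)

    def test_unknown_half_reaction(self):
        with pytest.raises(MissingCapacityError):
            oxidant_ratio("ClO4- -> Cl-")
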