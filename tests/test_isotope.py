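"""δ-notation arithmetic and the closed-system Rayleigh model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from methanox.isotope import (
    VPDB,
    DeltaValue,
    IncompatibleReferenceError,
    InsufficientDataError,
    InvalidDeltaError,
    InvalidRatioError,
    IsotopeStandard,
    RayleighObservation,
    UndefinedMixtureError,
    atom_fraction_to_delta,
    delta_to_atom_fraction,
    delta_to_ratio,
    discrimination,
    ratio_to_atom_fraction,
    ratio_to_delta,
    rayleigh_fit_alpha,
    rayleigh_forward,
    two_endmember_mix,
)


class TestDeltaConversions:
    @pytest.mark.parametrize(
        "delta, expected",
        [
            (0.0, 0.0111796),  # δ = 0 recovers the standard's ratio
            (1000.0, 0.0223592),  # doubling
            (-500.0, 0.0055898),  # halving
        ],
    )
    def test_delta_to_ratio(self, delta, expected):
        assert delta_to_ratio(DeltaValue(delta)) == pytest.approx(expected, rel=1e-12)

    def test_delta_at_minus_1000_rejected(self):
        with pytest.raises(InvalidDeltaError):
            DeltaValue(-1000.0)
        with pytest.raises(InvalidDeltaError):
            DeltaValue(float("nan"))

    @pytest.mark.parametrize(
        "ratio, expected",
        [
            (0.0, 0.0),
            (1.0, 0.5),
            # R/(1+R) for the VPDB ratio, frozen from exact rational arithmetic
            (0.0111796, 0.011055998360726423),
        ],
    )
    def test_ratio_to_atom_fraction(self, ratio, expected):
        assert ratio_to_atom_fraction(ratio) == pytest.approx(expected, abs=1e-15)

    def test_atom_fraction_matches_rational_oracle(self):
        from fractions import Fraction

        r = Fraction(111796, 10**7)
        oracle = r / (1 + r)
        assert ratio_to_atom_fraction(0.0111796) == pytest.approx(
            float(oracle), rel=1e-14
        )

    def test_negative_ratio_rejected(self):
        with pytest.raises(InvalidRatioError):
            ratio_to_atom_fraction(-0.1)
        with pytest.raises(InvalidRatioError):
            ratio_to_delta(-1e-9)

    def test_atom_fraction_increasing_in_ratio(self):
        ratios = np.linspace(0, 0.1, 50)
        fractions = [ratio_to_atom_fraction(r) for r in ratios]
        assert np.all(np.diff(fractions) > 0)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-110.0, max_value=2000.0))
    def test_round_trip_delta_ratio_fraction(self, delta):
        """δ → R → F → R → δ closes to well below measurement precision."""
        d = DeltaValue(delta)
        fraction = ratio_to_atom_fraction(delta_to_ratio(d))
        back = atom_fraction_to_delta(fraction)
        assert back.value == pytest.approx(delta, abs=1e-9)


class TestRayleighForward:
    def test_no_consumption_returns_source(self):
        d0 = DeltaValue(-50.0, "CH4")
        assert rayleigh_forward(d0, 1.005, 1.0).value == d0.value

    def test_no_fractionation_returns_source(self):
        d0 = DeltaValue(-50.0, "CH4")
        assert rayleigh_forward(d0, 1.0, 0.01).value == pytest.approx(d0.value)

    def test_strong_consumption_enriches_residual(self):
        # frozen from 30-digit evaluation of (δ0+1000)·f^(1/α−1) − 1000
        value = rayleigh_forward(DeltaValue(-50.0, "CH4"), 1.005, 0.01).value
        assert value == pytest.approx(-27.9830145483643, abs=1e-9)

    @pytest.mark.parametrize("f", [0.0, -0.5, 1.0001])
    def test_domain_errors(self, f):
        with pytest.raises(ValueError):
            rayleigh_forward(DeltaValue(-50.0), 1.005, f)

    @settings(derandomize=True, max_examples=100)
    @given(
        alpha=st.floats(min_value=1.0005, max_value=1.08),
        delta0=st.floats(min_value=-80.0, max_value=-20.0),
    )
    def test_monotone_in_f_and_continuous_at_alpha_one(self, alpha, delta0):
        d0 = DeltaValue(delta0, "CH4")
        fs = np.geomspace(1e-3, 1.0, 25)
        deltas = [rayleigh_forward(d0, alpha, f).value for f in fs]
        assert np.all(np.diff(deltas) <= 1e-12)  # enrichment as f decreases
        near_one = rayleigh_forward(d0, 1.0 + 1e-12, 0.01).value
        assert near_one == pytest.approx(delta0, abs=1e-6)


class TestRayleighFit:
    F_GRID = (1.0, 0.5, 0.1, 0.05, 0.01)

    def test_recovers_alpha_from_forward_data(self):
        d0 = DeltaValue(-50.0, "CH4")
        obs = [
            RayleighObservation(f, rayleigh_forward(d0, 1.005, f))
            for f in self.F_GRID
        ]
        fit = rayleigh_fit_alpha(obs, d0)
        assert fit.alpha == pytest.approx(1.005, rel=1e-12)
        assert fit.alpha_signed_convention == pytest.approx(-1.005, rel=1e-12)
        assert fit.epsilon == pytest.approx((1 / 1.005 - 1) * 1000, rel=1e-9)
        assert fit.rmse < 1e-9

    def test_constant_delta_gives_alpha_one(self):
        d0 = DeltaValue(-50.0, "CH4")
        obs = [RayleighObservation(f, d0) for f in (1.0, 0.5, 0.1)]
        fit = rayleigh_fit_alpha(obs, d0)
        assert fit.alpha == pytest.approx(1.0, abs=1e-14)
        assert fit.epsilon == pytest.approx(0.0, abs=1e-11)

    def test_two_point_exact_inversion(self):
        d0 = DeltaValue(-50.0, "CH4")
        obs = [
            RayleighObservation(1.0, d0),
            RayleighObservation(0.01, DeltaValue(-27.9830145483643, "CH4")),
        ]
        assert rayleigh_fit_alpha(obs, d0).alpha == pytest.approx(1.005, rel=1e-12)

    def test_insufficient_distinct_fractions(self):
        d0 = DeltaValue(-50.0)
        with pytest.raises(InsufficientDataError):
            rayleigh_fit_alpha([RayleighObservation(0.5, d0)], d0)
        with pytest.raises(InsufficientDataError):
            rayleigh_fit_alpha(
                [RayleighObservation(0.5, d0), RayleighObservation(0.5, d0)], d0
            )

    def test_positive_sign_convention(self):
        d0 = DeltaValue(-50.0, "CH4")
        obs = [
            RayleighObservation(f, rayleigh_forward(d0, 1.02, f))
            for f in (1.0, 0.3, 0.05)
        ]
        fit = rayleigh_fit_alpha(obs, d0, sign_convention="positive")
        assert fit.alpha_signed_convention == pytest.approx(fit.alpha)

    @settings(derandomize=True, max_examples=150, deadline=None)
    @given(
        alpha=st.floats(min_value=1.0005, max_value=1.08),
        delta0=st.floats(min_value=-80.0, max_value=-20.0),
        n=st.integers(min_value=3, max_value=8),
    )
    def test_noise_free_recovery_property(self, alpha, delta0, n):
        d0 = DeltaValue(delta0, "CH4")
        fs = np.geomspace(0.005, 1.0, n)
        obs = [RayleighObservation(f, rayleigh_forward(d0, alpha, f)) for f in fs]
        fit = rayleigh_fit_alpha(obs, d0)
        assert abs(fit.alpha - alpha) / alpha <= 1e-10


class TestDiscriminationAndMixing:
    def test_discrimination_examples(self):
        ch4 = DeltaValue(-50.0, "CH4")
        dic = DeltaValue(1.0, "DIC")
        assert discrimination(ch4, dic) == pytest.approx(-51.0)
        assert discrimination(ch4, ch4) == 0.0
        assert discrimination(DeltaValue(-30.0), DeltaValue(-50.0)) == pytest.approx(20.0)

    def test_discrimination_requires_same_standard(self):
        other = IsotopeStandard("other", 0.0112)
        with pytest.raises(IncompatibleReferenceError):
            discrimination(DeltaValue(0.0), DeltaValue(0.0, reference=other))

    def test_mix_pure_endmember(self):
        d1, d2 = DeltaValue(-47.0, "CH4"), DeltaValue(-19.0, "CH4")
        assert two_endmember_mix(d1, d2, 1.0, 5.0, 5.0).delta.value == pytest.approx(
            d1.value
        )

    def test_delta_linear_midpoint(self):
        d1, d2 = DeltaValue(-47.0, "CH4"), DeltaValue(-19.0, "CH4")
        result = two_endmember_mix(d1, d2, 0.5, 2.0, 2.0, mode="delta-linear")
        assert result.delta.value == pytest.approx(-33.0)
        assert result.mode == "delta-linear"

    def test_self_mix_is_identity(self):
        d = DeltaValue(-33.0, "CH4")
        result = two_endmember_mix(d, d, 0.4, 3.0, 7.0)
        assert result.delta.value == pytest.approx(d.value, abs=1e-9)

    def test_both_zero_concentration_rejected(self):
        with pytest.raises(UndefinedMixtureError):
            two_endmember_mix(DeltaValue(-47.0), DeltaValue(-19.0), 0.5, 0.0, 0.0)

    @settings(derandomize=True, max_examples=150)
    @given(
        d1=st.floats(min_value=-90.0, max_value=50.0),
        d2=st.floats(min_value=-90.0, max_value=50.0),
        frac=st.floats(min_value=0.0, max_value=1.0),
        c1=st.floats(min_value=0.01, max_value=2000.0),
        c2=st.floats(min_value=0.01, max_value=2000.0),
    )
    def test_atom_fraction_mixing_conserves_isotope_masses(
        self, d1, d2, frac, c1, c2
    ):
        """Mixture ¹³C and ¹²C inventories equal the summed end-member ones."""
        e1, e2 = DeltaValue(d1, "CH4"), DeltaValue(d2, "CH4")
        mixed = two_endmember_mix(e1, e2, frac, c1, c2).delta
        w1, w2 = frac * c1, (1 - frac) * c2
        # independent two-isotope mass balance oracle
        heavy = w1 * delta_to_atom_fraction(e1) + w2 * delta_to_atom_fraction(e2)
        light = (w1 + w2) - heavy
        if light <= 0:
            return
        oracle = ratio_to_delta(heavy / light).value
        assert mixed.value == pytest.approx(oracle, abs=1e-9)
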