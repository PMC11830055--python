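import numpy as np
import pytest

from dkrfiber import (
    BulkState,
    DimensionlessParameters,
    DomainError,
    HpmOrder,
    InvalidParameterError,
    SingularParameterError,
    conversion_degree,
    ode_residual,
    s1_hpm,
    s1_hpm_conversion,
    s2_hpm,
    s2_hpm_conversion,
)
from conftest import random_parameter_sets


class TestS1Series:
    def test_outer_wall_value_is_built_in(self, p_strong_diffusion):
        assert s1_hpm(2.0, p_strong_diffusion) == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "phi2, b0, theta, xi1, xi2, expected",
        [
            (0.5, 8.68, 3.27, 2.0, 0.03, 0.983742),
            (0.5, 34.72, 3.27, 2.0, 0.03, 0.994948),
            (1.0, 17.34, 5.0, 7.23, 0.25, 0.992697),
            (10.0, 17.34, 5.0, 7.23, 0.25, 0.929310),
        ],
    )
    def test_reference_values_at_inner_wall(self, phi2, b0, theta, xi1, xi2, expected):
        p = DimensionlessParameters(
            phi2=phi2, b0=b0, theta=theta, xi1=xi1, xi2=xi2, phi_frac=1.0
        )
        assert round(s1_hpm(1.0, p, HpmOrder.SECOND), 6) == expected

    def test_singularity_guard_near_b0_two(self):
        p = DimensionlessParameters(phi2=0.5, b0=2.0, theta=1.0)
        with pytest.raises(SingularParameterError):
            s1_hpm(1.5, p)

    def test_domain_guard(self, p_weak_diffusion):
        with pytest.raises(DomainError):
            s1_hpm(0.5, p_weak_diffusion)

    def test_boundary_conditions_over_random_parameters(self, rng):
        """Value 1 at x = 2 and zero slope at x = 1, for both species,
        across a random sample of admissible parameter sets."""
        eps = 1e-6
        for p in random_parameter_sets(rng, 25):
            for fn in (s1_hpm, s2_hpm):
                assert fn(2.0, p) == pytest.approx(1.0, abs=1e-10)
                slope = (fn(1.0 + eps, p) - fn(1.0, p)) / eps
                scale = max(1.0, abs(fn(1.0, p) - 1.0) / eps)
                assert abs(slope) <= 1e-6 * scale

    def test_residual_decays_with_at_least_second_order_in_phi2(self):
        """Plugging the truncated (S)-ester series into its governing
        equation (with the (R)-ester series supplying the inhibition
        coupling), the defect must shrink at least quadratically as Phi^2
        is halved. The (R)-ester equation is excluded: its printed series
        is first-order accurate by construction."""
        p0 = DimensionlessParameters(
            phi2=0.5, b0=8.68, theta=3.27, gamma=10.0, xi1=2.0, xi2=0.03,
            phi_frac=1.0,
        )
        xs = np.linspace(1.001, 1.999, 31)
        h = 1e-3
        phi2s = p0.phi2 / 2 ** np.arange(0, 5)
        norms = []
        zeros = np.zeros_like(xs)
        for phi2 in phi2s:
            p = p0.replace(phi2=float(phi2))
            s1 = s1_hpm(xs, p)
            ds1 = (s1_hpm(xs + h, p) - s1_hpm(xs - h, p)) / (2 * h)
            d2s1 = (s1_hpm(xs + h, p) - 2 * s1 + s1_hpm(xs - h, p)) / h**2
            r1, _ = ode_residual(
                xs, (s1, s2_hpm(xs, p)), (ds1, zeros), (d2s1, zeros), p
            )
            norms.append(np.max(np.abs(r1)))
        fit_slope = np.polyfit(np.log(phi2s), np.log(norms), 1)[0]
        assert fit_slope >= 1.95
        assert np.all(np.diff(np.log(norms)) / np.diff(np.log(phi2s)) >= 1.9)

    def test_first_order_truncation_drops_quartic_term(self, p_strong_diffusion):
        first = s1_hpm(1.0, p_strong_diffusion, HpmOrder.FIRST)
        second = s1_hpm(1.0, p_strong_diffusion, HpmOrder.SECOND)
        assert first != second
        # the quartic term halves four times as fast
        p_half = p_strong_diffusion.replace(phi2=p_strong_diffusion.phi2 / 2)
        ratio = (s1_hpm(1.0, p_half, HpmOrder.FIRST) - 1.0) / (first - 1.0)
        assert ratio == pytest.approx(0.5, rel=1e-12)


class TestS2Series:
    def test_no_racemization_means_uniform_profile(self, p_strong_diffusion):
        p = p_strong_diffusion.replace(gamma=0.0)
        xs = np.linspace(1, 2, 11)
        assert np.allclose(s2_hpm(xs, p), 1.0, atol=1e-15)

    def test_orders_coincide(self, p_strong_diffusion):
        assert s2_hpm(1.3, p_strong_diffusion, HpmOrder.FIRST) == s2_hpm(
            1.3, p_strong_diffusion, HpmOrder.SECOND
        )

    def test_linear_in_gamma(self, p_weak_diffusion):
        base = s2_hpm(1.0, p_weak_diffusion) - 1.0
        doubled = s2_hpm(1.0, p_weak_diffusion.replace(gamma=2.0)) - 1.0
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_accumulates_above_unity_for_reference_sets(
        self, p_weak_diffusion, p_strong_diffusion
    ):
        xs = np.linspace(1, 2, 21)
        for p in (p_weak_diffusion, p_strong_diffusion):
            values = s2_hpm(xs, p)
            assert np.all(values[:-1] > 1.0)
            assert np.all(np.diff(values) < 0)


class TestConversionDegree:
    def test_map(self):
        assert conversion_degree(1.0, 1.0) == 0.0
        assert conversion_degree(1.0, 0.0) == 1.0
        assert conversion_degree(2.0, 1.0) == 0.5
        with pytest.raises(InvalidParameterError):
            conversion_degree(0.0, 1.0)

    def test_first_order_terms_of_both_s1_forms_agree_at_zero_conversion(
        self, rng
    ):
        """At X = 0 and racemic unit bulk, the conversion-degree series and
        the standard series share their leading (Phi^2) term exactly; the
        printed second-order terms differ by the factor (1 + Theta)/Theta,
        so the comparison is made on the Phi^2-linear part alone."""
        b = BulkState(1.0, 1.0, 0.0)
        xs = np.linspace(1.0, 2.0, 17)
        for p in random_parameter_sets(rng, 10):
            eps_p = p.replace(phi2=1e-6)
            lead_conv = s1_hpm_conversion(xs, eps_p, b) - 1.0
            lead_std = s1_hpm(xs, eps_p, HpmOrder.FIRST) - 1.0
            # at phi2 = 1e-6 the quartic contamination is ~1e-8 relative
            assert np.allclose(lead_conv, lead_std, rtol=1e-6, atol=1e-25)

    def test_printed_second_order_terms_differ_by_theta_factor(
        self, p_weak_diffusion
    ):
        """Documented discrepancy: the printed conversion-degree series is
        not identical to the standard series at X = 0 -- its quartic term is
        exactly (1 + Theta)/Theta times larger."""
        b = BulkState(1.0, 1.0, 0.0)
        xs = np.linspace(1.0, 2.0, 9)[:-1]
        p = p_weak_diffusion
        quartic_std = s1_hpm(xs, p, HpmOrder.SECOND) - s1_hpm(xs, p, HpmOrder.FIRST)
        full_conv = s1_hpm_conversion(xs, p, b) - 1.0
        lead = s1_hpm(xs, p, HpmOrder.FIRST) - 1.0
        quartic_conv = full_conv - lead
        factor = (1.0 + p.theta) / p.theta
        assert np.allclose(quartic_conv, factor * quartic_std, rtol=1e-9)

    def test_outer_wall_value_preserved(self, p_weak_diffusion):
        b = BulkState(s1b=2.0, s2b=1.5, x_conv=0.3)
        assert s1_hpm_conversion(2.0, p_weak_diffusion, b) == pytest.approx(
            1.0, abs=1e-12
        )

    def test_conversion_guard(self, p_weak_diffusion):
        with pytest.raises(InvalidParameterError):
            BulkState(1.0, 1.0, 1.2)


class TestS2ConversionForm:
    def test_zero_gamma_is_uniform(self, p_weak_diffusion):
        p = p_weak_diffusion.replace(gamma=0.0)
        b = BulkState(2.0, 1.5, 0.4)
        xs = np.linspace(1, 2, 7)
        assert np.allclose(s2_hpm_conversion(xs, p, b), 1.0, atol=1e-15)

    def test_zero_drive_locus_is_uniform(self, p_strong_diffusion):
        # the driving factor 1 + S1b (X - 1) vanishes at X = 0, S1b = 1
        b = BulkState(1.0, 2.0, 0.0)
        xs = np.linspace(1, 2, 7)
        assert np.allclose(s2_hpm_conversion(xs, p_strong_diffusion, b), 1.0, atol=1e-15)

    def test_gamma_and_gamma_squared_structure(self, p_weak_diffusion):
        b = BulkState(2.0, 1.5, 0.3)
        x = 1.2
        d1 = s2_hpm_conversion(x, p_weak_diffusion.replace(gamma=1.0), b) - 1.0
        d2 = s2_hpm_conversion(x, p_weak_diffusion.replace(gamma=2.0), b) - 1.0
        d4 = s2_hpm_conversion(x, p_weak_diffusion.replace(gamma=4.0), b) - 1.0
        # d(g) = a g + c g^2: d4 - 2 d2 = 8 c isolates the quadratic part,
        # and consistency of the middle point checks the pure structure
        c = (d4 - 2 * d2) / 8.0
        a = d1 - c
        assert d2 == pytest.approx(2 * a + 4 * c, rel=1e-10)
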