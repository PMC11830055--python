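import numpy as np
import pytest

from dkrfiber import (
    BulkState,
    DimensionlessParameters,
    HpmOrder,
    MiefVariant,
    local_effectiveness,
    mief_closed_form,
    mief_quadrature,
    mief_zero_thiele_limit,
    s1_hpm,
    s2_hpm,
)
from dkrfiber.effectiveness import mief_linear_form
from dkrfiber.reference import (
    MIEF_TABLE2,
    MIEF_TABLE2_THETA,
    MIEF_TABLE3,
    MIEF_TABLE_BASE,
)


def mief_params(m, theta):
    return DimensionlessParameters(phi2=m**2, theta=theta, **MIEF_TABLE_BASE)


class TestZeroThieleLimit:
    def test_racemic_reference_state_is_unity(self, p_mief_base):
        res = mief_zero_thiele_limit(p_mief_base, BulkState(1.0, 1.0))
        assert res.eta_m == pytest.approx(1.0, abs=1e-15)

    @pytest.mark.parametrize(
        "s1b, expected", [(1.5, 6.5 / 9.0), (2.0, 7.0 / 12.0)]
    )
    def test_bulk_enrichment_reduces_effectiveness(self, p_mief_base, s1b, expected):
        res = mief_zero_thiele_limit(p_mief_base, BulkState(s1b, 1.0))
        assert res.eta_m == pytest.approx(expected, rel=1e-12)

    def test_equals_rate_ratio(self, p_mief_base):
        from dkrfiber import reaction_rate_s1

        b = BulkState(1.7, 1.3)
        eta0 = mief_zero_thiele_limit(p_mief_base, b).eta_m
        ratio = reaction_rate_s1(1.0, 1.0, p_mief_base) / reaction_rate_s1(
            b.s1b, b.s2b, p_mief_base
        )
        assert eta0 == pytest.approx(ratio, rel=1e-12)


class TestClosedForms:
    def test_zero_thiele_recovers_eta0_exactly(self, racemic_bulk):
        p = DimensionlessParameters(phi2=0.0, theta=5.0, **MIEF_TABLE_BASE)
        for variant in (MiefVariant.PRINTED_EQ22, MiefVariant.TABLE_CONSISTENT):
            res = mief_closed_form(p, racemic_bulk, variant)
            assert res.eta_m == pytest.approx(1.0, abs=1e-14)

    def test_linear_and_decreasing_in_phi2(self, racemic_bulk):
        for variant in (MiefVariant.PRINTED_EQ22, MiefVariant.TABLE_CONSISTENT):
            etas = [
                mief_closed_form(
                    mief_params(0.0, 5.0).replace(phi2=phi2), racemic_bulk, variant
                ).eta_m
                for phi2 in (0.0, 1.0, 2.0, 3.0)
            ]
            diffs = np.diff(etas)
            assert np.all(diffs < 0)
            assert np.allclose(diffs, diffs[0], rtol=1e-12)

    def test_bracket_form_equals_linear_factorisation(self, racemic_bulk, rng):
        """The transcribed closed form and its eta0*(1 - K*Phi^2)
        factorisation are the same function."""
        for _ in range(20):
            p = DimensionlessParameters(
                phi2=float(rng.uniform(0, 50)),
                b0=float(rng.uniform(3, 40)),
                theta=float(rng.uniform(0.2, 20)),
                xi1=float(rng.uniform(0, 10)),
                xi2=float(rng.uniform(0, 10)),
                phi_frac=float(rng.uniform(0, 2)),
            )
            b = BulkState(float(rng.uniform(0.5, 5)), float(rng.uniform(0.5, 5)))
            for variant in (MiefVariant.PRINTED_EQ22, MiefVariant.TABLE_CONSISTENT):
                assert mief_closed_form(p, b, variant).eta_m == pytest.approx(
                    mief_linear_form(p, b, variant), rel=1e-10
                )

    def test_table_consistent_variant_reproduces_all_published_cells(self):
        """All 32 cells of the two published effectiveness tables, with the
        header value m entering as Phi^2 = m**2."""
        for m, cells in MIEF_TABLE2.items():
            for s1b, printed in cells:
                eta = mief_closed_form(
                    mief_params(m, MIEF_TABLE2_THETA), BulkState(s1b, 1.0)
                ).eta_m
                assert eta == pytest.approx(printed, abs=5e-5)
        for m, cells in MIEF_TABLE3.items():
            for theta, printed in cells:
                eta = mief_closed_form(
                    mief_params(m, theta), BulkState(1.0, 1.0)
                ).eta_m
                assert eta == pytest.approx(printed, abs=5e-5)

    def test_printed_variant_does_not_reproduce_the_tables(self):
        """Documented discrepancy: the literally transcribed closed form
        misses the published cells by far more than the table tolerance."""
        eta = mief_closed_form(
            mief_params(10.0, MIEF_TABLE2_THETA),
            BulkState(1.0, 1.0),
            MiefVariant.PRINTED_EQ22,
        ).eta_m
        assert abs(eta - 0.433430) > 0.05
        assert eta == pytest.approx(0.347, abs=5e-3)

    def test_phi_and_xi2_enter_only_as_product(self, racemic_bulk):
        p1 = mief_params(2.0, 5.0).replace(phi_frac=0.5, xi2=0.8)
        p2 = mief_params(2.0, 5.0).replace(phi_frac=0.8, xi2=0.5)
        for variant in (MiefVariant.PRINTED_EQ22, MiefVariant.TABLE_CONSISTENT):
            assert mief_closed_form(p1, racemic_bulk, variant).eta_m == pytest.approx(
                mief_closed_form(p2, racemic_bulk, variant).eta_m, rel=1e-14
            )


class TestLocalEffectiveness:
    def test_outer_wall_concentration_definition(self, p_mief_base, racemic_bulk):
        profile = lambda x: (s1_hpm(x, p_mief_base), s2_hpm(x, p_mief_base))
        assert local_effectiveness(
            2.0, profile, p_mief_base, racemic_bulk, "concentration"
        ) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_profile_is_fully_effective(self, p_mief_base, racemic_bulk):
        profile = lambda x: (np.ones_like(np.asarray(x, float)),) * 2
        for definition in ("rate", "concentration"):
            assert local_effectiveness(
                1.3, profile, p_mief_base, racemic_bulk, definition
            ) == pytest.approx(1.0, abs=1e-14)

    def test_rate_definition_matches_zero_thiele_limit(self, p_mief_base):
        """With a uniform unit profile, the rate ratio against an enriched
        bulk equals the zero-Thiele closed-form limit (7/12 at S1b = 2)."""
        profile = lambda x: (1.0, 1.0)
        b = BulkState(2.0, 1.0)
        eta = local_effectiveness(1.5, profile, p_mief_base, b, "rate")
        assert eta == pytest.approx(7.0 / 12.0, rel=1e-12)


class TestQuadrature:
    def test_uniform_profile_normalisation(self, p_mief_base, racemic_bulk):
        profile = lambda x: (np.ones_like(np.asarray(x, float)),) * 2
        for definition in ("rate", "concentration"):
            res = mief_quadrature(p_mief_base, racemic_bulk, profile, definition)
            assert res.eta_m == pytest.approx(1.0, abs=1e-12)

    def test_against_trapezoid_oracle(self, p_mief_base, racemic_bulk):
        profile = lambda x: (s1_hpm(x, p_mief_base), s2_hpm(x, p_mief_base))
        res = mief_quadrature(p_mief_base, racemic_bulk, profile, "rate")
        xs = np.linspace(1.0, 2.0, 100001)
        from dkrfiber import local_effectiveness as leff

        integrand = xs * np.asarray(
            leff(xs, profile, p_mief_base, racemic_bulk, "rate")
        )
        brute = 2.0 * np.trapezoid(integrand, xs) / 3.0
        assert res.eta_m == pytest.approx(brute, abs=1e-8)

    def test_rate_quadrature_close_to_table_consistent_form_at_small_phi2(
        self, racemic_bulk
    ):
        """At Phi^2 <= 1 the rate-definition quadrature over the first-order
        series agrees with the table-consistent closed form to 2e-4
        relative."""
        for phi2 in (0.25, 0.5, 1.0):
            p = mief_params(0.0, MIEF_TABLE2_THETA).replace(phi2=phi2)
            profile = lambda x: (
                s1_hpm(x, p, HpmOrder.FIRST),
                np.ones_like(np.asarray(x, float)),
            )
            quad_eta = mief_quadrature(p, racemic_bulk, profile, "rate").eta_m
            closed = mief_closed_form(p, racemic_bulk).eta_m
            assert quad_eta == pytest.approx(closed, rel=2e-4)

    def test_deficit_coefficient_value(self, racemic_bulk):
        """d(eta_m)/d(Phi^2) of the table-consistent form at the published
        effectiveness-table base parameters is about -5.666e-3."""
        p0 = mief_params(0.0, MIEF_TABLE2_THETA)
        p1 = p0.replace(phi2=1.0)
        slope = (
            mief_closed_form(p1, racemic_bulk).eta_m
            - mief_closed_form(p0, racemic_bulk).eta_m
        )
        assert slope == pytest.approx(-5.666e-3, abs=2e-6)
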