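"""Local and mean integrated effectiveness factors for the (S)-ester.

The local effectiveness factor eta(x) compares the reaction state inside the
membrane annulus with the bulk/surface state, under either of two published
definitions:

* ``rate``: v(S1(x), S2(x)) / v(S1b, S2b) with v the inhibited
  Michaelis-Menten rate law;
* ``concentration``: S1(x) / S1(at the bulk interface), the interface value
  being S1(2) = 1 under the Dirichlet outer condition.

The mean integrated effectiveness factor (MIEF) is the cross-section average
over the annulus (inner radius x = 1, outer x = 2):

    eta_m = 2 * Int_1^2 x * eta(x) dx / (2^2 - 1^2)

Two closed forms are provided. ``printed_eq22`` is the published expression
transcribed literally. ``table_consistent`` differs in a single bracket
coefficient (9*Phi^2/2 in place of 9*Phi^2/4) and is the variant that
actually regenerates all 32 published MIEF table cells; the mismatch of the
literal form is a documented discrepancy, not adjudicated here. Both are
algebraically of the form eta0 * (1 - K * Phi^2), linear and decreasing in
Phi^2, with eta0 the zero-Thiele (kinetic-control) limit.

Modulus convention: the MIEF tables tabulate a column header m whose deficit
scales as m^2, i.e. the header enters the closed forms as Phi^2 = m**2. The
profile tables use their stated Phi^2 literally. Callers choose explicitly;
nothing is guessed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .exceptions import InvalidParameterError
from .model_core import BulkState, DimensionlessParameters, reaction_rate_s1


class MiefVariant(enum.Enum):
    PRINTED_EQ22 = "printed"
    TABLE_CONSISTENT = "table-consistent"
    QUADRATURE_RATE = "quadrature-rate"
    QUADRATURE_CONCENTRATION = "quadrature-concentration"
    ZERO_THIELE_LIMIT = "zero-thiele"


@dataclass(frozen=True)
class EffectivenessResult:
    """A mean integrated effectiveness factor and how it was obtained."""

    eta_m: float
    variant: MiefVariant
    parameters: DimensionlessParameters
    bulk: BulkState

    def __post_init__(self) -> None:
        if not np.isfinite(self.eta_m):
            raise InvalidParameterError(f"eta_m must be finite, got {self.eta_m!r}")


def local_effectiveness(
    x,
    profile,
    p: DimensionlessParameters,
    b: BulkState,
    definition: str = "rate",
):
    """Local effectiveness factor at radius x.

    ``profile`` is a callable x -> (s1, s2), e.g. a numeric
    :class:`~dkrfiber.bvp.ConcentrationProfile` or a closure over the closed
    forms. ``definition`` selects the rate ratio or the concentration ratio.
    """
    s1, s2 = profile(x)
    if definition == "concentration":
        return np.asarray(s1, dtype=float) / 1.0  # S1 at bulk interface = S1(2) = 1
    if definition == "rate":
        v_bulk = reaction_rate_s1(b.s1b, b.s2b, p)
        if v_bulk == 0:
            raise InvalidParameterError(
                "bulk reaction rate is zero; rate-ratio effectiveness undefined"
            )
        return reaction_rate_s1(s1, s2, p) / v_bulk
    raise InvalidParameterError(f"unknown definition {definition!r}")


def mief_quadrature(
    p: DimensionlessParameters,
    b: BulkState,
    profile,
    definition: str = "rate",
) -> EffectivenessResult:
    """MIEF by adaptive quadrature of the local factor over the annulus."""
    def integrand(x):
        return x * float(
            np.asarray(local_effectiveness(x, profile, p, b, definition))
        )

    integral, err = quad(integrand, 1.0, 2.0, epsabs=1e-12, epsrel=1e-12, limit=200)
    if err > 1e-10:
        raise InvalidParameterError(
            f"quadrature error estimate {err:.3g} exceeds 1e-10"
        )
    variant = (
        MiefVariant.QUADRATURE_RATE
        if definition == "rate"
        else MiefVariant.QUADRATURE_CONCENTRATION
    )
    return EffectivenessResult(2.0 * integral / 3.0, variant, p, b)


def mief_zero_thiele_limit(
    p: DimensionlessParameters,
    b: BulkState,
) -> EffectivenessResult:
    """Kinetic-control limit eta0 of the MIEF as Phi^2 -> 0.

    eta0 = (Theta + S1b)(1 + S2b*xi1 + phi*xi2)
           / (S1b (1 + xi1 + phi*xi2)(Theta + 1)),
    which equals the rate ratio v(1, 1)/v(S1b, S2b); unity at the racemic
    reference state S1b = S2b = 1.
    """
    eta0 = _eta0(p, b)
    return EffectivenessResult(eta0, MiefVariant.ZERO_THIELE_LIMIT, p, b)


def _eta0(p: DimensionlessParameters, b: BulkState) -> float:
    if not b.s1b > 0:
        raise InvalidParameterError(f"s1b must be > 0, got {b.s1b!r}")
    num = (p.theta + b.s1b) * (1.0 + b.s2b * p.xi1 + p.phi_frac * p.xi2)
    den = b.s1b * (1.0 + p.xi1 + p.phi_frac * p.xi2) * (p.theta + 1.0)
    return num / den


def _deficit_coefficient(p: DimensionlessParameters, variant: MiefVariant) -> float:
    """K in eta_m = eta0 * (1 - K * Phi^2) for either closed-form variant."""
    b0, theta = p.b0, p.theta
    d = 1.0 + p.xi1 + p.phi_frac * p.xi2
    half_coeff = 9.0 / 4.0 if variant is MiefVariant.PRINTED_EQ22 else 9.0 / 2.0
    two_nb = float(np.exp(-b0 * np.log(2.0)))
    k0 = (
        3.0 * two_nb * b0
        - half_coeff * b0
        + 2.0 * two_nb
        - 2.0
        + 9.0 / 4.0 * b0**2
    )
    return theta**2 * k0 / (3.0 * d * (theta + 1.0) ** 2 * b0 * (b0**2 - 4.0))


def _mief_bracket(
    p: DimensionlessParameters, b: BulkState, half_coeff: float
) -> float:
    """The literal published closed form, with the contested bracket
    coefficient (9*Phi^2/half_divisor) injected; used as a transcription-level
    cross-check of the eta0*(1 - K*Phi^2) factorisation."""
    b0, theta, phi2 = p.b0, p.theta, p.phi2
    xi1, xi2, phif = p.xi1, p.xi2, p.phi_frac
    two_nb = float(np.exp(-b0 * np.log(2.0)))
    bracket = (
        3.0 * two_nb * b0 * theta**2 * phi2
        - 3.0 * (1.0 + xi1 + phif * xi2) * (theta + 1.0) ** 2 * b0**3
        + (
            12.0 * (theta + 1.0) ** 2 * xi1
            + 12.0 * phif * xi2 * (theta + 1.0) ** 2
            + (12.0 - half_coeff * phi2) * theta**2
            + 24.0 * theta
            + 12.0
        )
        * b0
        + (2.0 * two_nb - 2.0) * theta**2 * phi2
        + 9.0 * theta**2 * phi2 * b0**2 / 4.0
    )
    num = -(theta + b.s1b) * (1.0 + b.s2b * xi1 + phif * xi2) * bracket
    den = (
        3.0
        * b0
        * b.s1b
        * (b0 + 2.0)
        * (b0 - 2.0)
        * (1.0 + xi1 + phif * xi2) ** 2
        * (theta + 1.0) ** 3
    )
    return num / den


def mief_closed_form(
    p: DimensionlessParameters,
    b: BulkState,
    variant: MiefVariant = MiefVariant.TABLE_CONSISTENT,
) -> EffectivenessResult:
    """MIEF from a closed form: the literal published expression or the
    table-consistent correction of its single contested coefficient."""
    if variant not in (MiefVariant.PRINTED_EQ22, MiefVariant.TABLE_CONSISTENT):
        raise InvalidParameterError(f"not a closed-form variant: {variant!r}")
    p.require_regular_b0()
    half_coeff = 9.0 / 4.0 if variant is MiefVariant.PRINTED_EQ22 else 9.0 / 2.0
    eta_m = _mief_bracket(p, b, half_coeff)
    return EffectivenessResult(eta_m, variant, p, b)


def mief_linear_form(
    p: DimensionlessParameters,
    b: BulkState,
    variant: MiefVariant = MiefVariant.TABLE_CONSISTENT,
) -> float:
    """The same closed form via the factorisation eta0 * (1 - K * Phi^2).

    Algebraically identical to :func:`mief_closed_form`; kept as an
    independent route for testing the factorisation.
    """
    p.require_regular_b0()
    return _eta0(p, b) * (1.0 - _deficit_coefficient(p, variant) * p.phi2)
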