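"""Closed-form perturbation-series concentration profiles.

The coupled steady-state system is embedded in a homotopy indexed by an
artificial parameter p; solving the resulting cascade of linear radial
problems and truncating at O(p^3) gives closed-form profiles for both
enantiomers. The expressions here are transcribed term for term from the
published series, with no algebraic simplification, so that the reference
tables validate the transcription directly. Negative powers x**(-B0),
2**(-B0) and 4**(-B0) are evaluated through exp/log for stability at large
Bodenstein numbers.

Known transcription-level caveats (kept as printed, documented, tested):

* The second-order (R)-ester series (:func:`s2_hpm`) is the exact solution
  of the linearised racemization problem driven by the first-order (S)-ester
  deficit -- this was re-derived symbolically -- but it does *not* regenerate
  the published semi-analytical (R)-ester table columns, which evidently
  include further feedback corrections whose closed form was never printed.
* The conversion-degree (S)-ester form (:func:`s1_hpm_conversion`) reduces
  to :func:`s1_hpm` at X = 0, S1b = S2b = 1 in its first-order term only;
  its printed second-order term is larger by the factor (1 + Theta)/Theta.
"""

from __future__ import annotations

import enum

import numpy as np

from .exceptions import DomainError, InvalidParameterError
from .model_core import BulkState, DimensionlessParameters, _check_domain


class HpmOrder(enum.Enum):
    """Series truncation: ``first`` keeps O(p^1), ``second`` the full form."""

    FIRST = "first"
    SECOND = "second"


def _neg_pow(base, exponent):
    """base**(-exponent) via exp/log; base > 0."""
    return np.exp(-np.asarray(exponent, dtype=float) * np.log(base))


def _powers(x: np.ndarray, b0: float):
    """The recurring negative powers x^-B0, 2^-B0, 4^-B0 and x^(2-B0)."""
    x_nb = _neg_pow(x, b0)
    two_nb = float(_neg_pow(2.0, b0))
    four_nb = float(_neg_pow(4.0, b0))
    x_2mb = x**2 * x_nb
    return x_nb, two_nb, four_nb, x_2mb


def _as_result(x, values: np.ndarray):
    values = np.asarray(values)
    return float(values.reshape(-1)[0]) if np.ndim(x) == 0 else values


def s1_hpm(
    x,
    p: DimensionlessParameters,
    order: HpmOrder = HpmOrder.SECOND,
):
    """(S)-ester profile S1(x) from the truncated perturbation series.

    The first-order correction scales with Phi^2*Theta, the second-order one
    with Phi^4*Theta^3. Both vanish identically at the outer wall x = 2, so
    the bulk boundary value is built into the series.
    """
    p.require_regular_b0()
    x = _check_domain(x)
    b0, theta = p.b0, p.theta
    denom_inh = 1.0 + p.phi_frac * p.xi2 + p.xi1
    x_nb, two_nb, four_nb, x_2mb = _powers(np.atleast_1d(x), b0)
    xa = np.atleast_1d(np.asarray(x, dtype=float))

    term1 = (
        p.phi2
        * theta
        * (xa**2 * b0 - 4.0 * b0 - 2.0 * two_nb + 2.0 * x_nb)
        / (2.0 * b0 * (2.0 + b0) * (1.0 + theta) * denom_inh)
    )
    if order is HpmOrder.FIRST:
        return _as_result(x, 1.0 + term1)

    big = (
        (-4.0 * b0**3 - 24.0 * b0**2 - 32.0 * b0) * x_2mb
        + (
            (-8.0 * b0**2 - 16.0 * b0 + 64.0) * x_nb
            - 4.0 * xa**2 * b0**3
            - 8.0 * xa**2 * b0**2
            + 32.0 * xa**2 * b0
            + 40.0 * b0**3
            + 144.0 * b0**2
            - 96.0 * b0
            + 64.0
        )
        * two_nb
        + (-2.0 + b0)
        * (
            (-8.0 * b0**2 - 32.0 * b0 + 32.0) * x_nb
            + (8.0 * b0 + 32.0) * four_nb
            + ((xa**2 - 4.0) * b0 + 2.0 * xa**2 - 24.0) * (xa**2 - 4.0) * b0**2
        )
    )
    term2 = (
        p.phi2**2
        * theta**3
        * big
        / (
            8.0
            * b0**2
            * (4.0 + b0)
            * (-2.0 + b0)
            * (2.0 + b0) ** 2
            * (1.0 + theta) ** 3
            * denom_inh**2
        )
    )
    return _as_result(x, 1.0 + term1 + term2)


def _s2_kernel(xa: np.ndarray, b0: float):
    """Radial kernel of the (R)-ester correction (equals the S1 second-order
    kernel divided by 8, an identity verified symbolically)."""
    x_nb, two_nb, four_nb, x_2mb = _powers(xa, b0)
    return (
        (-3.0 * b0**2 - 4.0 * b0 - 0.5 * b0**3) * x_2mb
        + (
            (-(b0**2) - 2.0 * b0 + 8.0) * x_nb
            - xa**2 * b0**3 / 2.0
            - xa**2 * b0**2
            + 4.0 * xa**2 * b0
            + 5.0 * b0**3
            + 18.0 * b0**2
            - 12.0 * b0
            + 8.0
        )
        * two_nb
        + (-2.0 + b0)
        * (
            (-(b0**2) - 4.0 * b0 + 4.0) * x_nb
            + (b0 + 4.0) * four_nb
            + ((xa**2 - 4.0) * b0 + 2.0 * xa**2 - 24.0) * (xa**2 - 4.0) * b0**2 / 8.0
        )
    )


def s2_hpm(
    x,
    p: DimensionlessParameters,
    order: HpmOrder = HpmOrder.SECOND,
):
    """(R)-ester profile S2(x) from the perturbation series.

    The printed series carries a single correction term proportional to
    gamma*Phi^2*Theta (racemization driven by the (S)-ester deficit), so the
    first- and second-order truncations coincide.
    """
    p.require_regular_b0()
    x = _check_domain(x)
    del order  # single printed correction term: truncations coincide
    b0, theta = p.b0, p.theta
    denom_inh = 1.0 + p.phi_frac * p.xi2 + p.xi1
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    term = (
        p.gamma
        * p.phi2
        * theta
        * _s2_kernel(xa, b0)
        / (
            2.0
            * b0**2
            * (4.0 + b0)
            * (-2.0 + b0)
            * (2.0 + b0) ** 2
            * (1.0 + theta)
            * denom_inh
        )
    )
    return _as_result(x, 1.0 + term)


def conversion_degree(s1b: float, s1: float) -> float:
    """Conversion degree X = (S1b - S1)/S1b of the (S)-ester hydrolysis."""
    if not s1b > 0:
        raise InvalidParameterError(f"s1b must be > 0, got {s1b!r}")
    return (s1b - s1) / s1b


def s1_hpm_conversion(x, p: DimensionlessParameters, b: BulkState):
    """(S)-ester profile rewritten in terms of conversion degree and bulk state.

    Evaluates the published conversion-degree expression exactly as printed.
    At X = 0, S1b = S2b = 1 its first-order term coincides with
    :func:`s1_hpm`; the printed second-order term does not (see module notes).
    """
    p.require_regular_b0()
    x = _check_domain(x)
    if b.x_conv >= 1.0:
        raise DomainError("conversion degree X must be < 1")
    b0, theta = p.b0, p.theta
    X, s1b, s2b = b.x_conv, b.s1b, b.s2b
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    x_nb, two_nb, four_nb, x_2mb = _powers(xa, b0)

    d1 = (X - 1.0) * s1b - theta
    d2 = -1.0 - p.phi_frac * p.xi2 + (X - 1.0) * s2b * p.xi1
    term1 = (
        -p.phi2
        * theta
        * (-0.5 * xa**2 * b0 + 2.0 * b0 + two_nb - x_nb)
        / (b0 * (2.0 + b0) * d1 * d2)
    )
    big = (
        (0.5 * b0**3 + 3.0 * b0**2 + 4.0 * b0) * x_2mb
        + (
            (b0**2 + 2.0 * b0 - 8.0) * x_nb
            + 0.5 * xa**2 * b0**3
            + xa**2 * b0**2
            - 4.0 * xa**2 * b0
            - 5.0 * b0**3
            - 18.0 * b0**2
            + 12.0 * b0
            - 8.0
        )
        * two_nb
        - (-2.0 + b0)
        * (
            (-(b0**2) - 4.0 * b0 + 4.0) * x_nb
            + (b0 + 4.0) * four_nb
            + 0.125 * ((xa**2 - 4.0) * b0 + 2.0 * xa**2 - 24.0) * (xa**2 - 4.0) * b0**2
        )
    )
    term2 = (
        -p.phi2**2
        * theta**2
        * big
        / (b0**2 * (4.0 + b0) * (-2.0 + b0) * (2.0 + b0) ** 2 * d1**2 * d2**2)
    )
    return _as_result(x, 1.0 + term1 + term2)


def s2_hpm_conversion(x, p: DimensionlessParameters, b: BulkState):
    """(R)-ester profile in conversion-degree form, exactly as printed.

    Carries a first-order term in gamma and a second-order term in gamma^2,
    both proportional to (1 + S1b(X - 1)); at X = 0, S1b = 1 the driving
    factor vanishes and the profile is identically 1.
    """
    p.require_regular_b0()
    x = _check_domain(x)
    if b.x_conv >= 1.0:
        raise DomainError("conversion degree X must be < 1")
    b0 = p.b0
    X, s1b, s2b = b.x_conv, b.s1b, b.s2b
    if s1b + s2b <= 0:
        raise InvalidParameterError("s1b + s2b must be > 0")
    gamma = p.gamma
    xa = np.atleast_1d(np.asarray(x, dtype=float))
    x_nb, two_nb, four_nb, x_2mb = _powers(xa, b0)

    drive = 1.0 + s1b * (X - 1.0)
    pool = (s1b + s2b) * (X - 1.0)
    inner = (
        gamma * xa**2 * drive / 2.0
        + gamma
        * drive
        * ((2.0 + b0) * (X - 1.0) * (s2b + s1b) * x_nb - (two_nb + 2.0 * b0))
        / (
            b0
            * (
                s2b * X * b0
                + s1b * X * b0
                + 2.0 * s2b * X
                + 2.0 * s1b * X
                - s2b * b0
                - s1b * b0
                - 2.0 * s2b
                - 2.0 * s1b
            )
        )
    )
    term1 = inner / ((2.0 + b0) * pool)
    big = (
        (b0**3 + 6.0 * b0**2 + 8.0 * b0) * x_2mb
        + (
            (2.0 * b0**2 + 4.0 * b0 - 16.0) * x_nb
            + xa**2 * b0**3
            + 2.0 * xa**2 * b0**2
            - 8.0 * xa**2 * b0
            - 10.0 * b0**3
            - 36.0 * b0**2
            + 24.0 * b0
            - 16.0
        )
        * two_nb
        - (-2.0 + b0)
        * (
            (-2.0 * b0**2 - 8.0 * b0 + 8.0) * x_nb
            + (2.0 * b0 + 8.0) * four_nb
            + 0.25 * ((xa**2 - 4.0) * b0 + 2.0 * xa**2 - 24.0) * (xa**2 - 4.0) * b0**2
        )
    )
    term2 = (
        -(gamma**2)
        * drive
        * big
        / (2.0 * b0**2 * (4.0 + b0) * (-2.0 + b0) * (2.0 + b0) ** 2 * pool**2)
    )
    return _as_result(x, 1.0 + term1 + term2)
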