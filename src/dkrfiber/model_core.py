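"""Core model state: parameters, dimensionless groups, and governing residuals.

The reactor is a bundle of hollow fibers whose porous wall is loaded with
immobilised lipase. The (S)-ester of racemic ibuprofen ester is hydrolysed
enantioselectively while base-mediated racemization replenishes it from the
(R)-ester. At steady state, radial diffusion and convection through the
membrane annulus balance reaction, giving a coupled pair of second-order ODEs
on the dimensionless radius x in [1, 2]:

    S1'' + (1 + B0)/x * S1' = Phi^2 * S1 / ((1 + S1/Theta)(1 + phi*xi2 + xi1*S2))
    S2'' + (1 + B0)/x * S2' = gamma * (S1 - S2) / (S1 + S2)

with no-flux conditions at the inner wall (x = 1) and bulk concentration
(S1 = S2 = 1) imposed at the outer wall (x = 2). The Dirichlet outer
condition is the large-B0 reduction of the convective flux condition; the
underlying wall profile 1 - x**(-B0) is available through
:func:`robin_wall_profile` as a diagnostic for how good that reduction is.

All spatial modelling happens in dimensionless form; dimensional quantities
enter only through :class:`PhysicalParameters` and :func:`to_dimensionless`.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, fields

import numpy as np

from .exceptions import (
    DegenerateStateError,
    DomainError,
    InvalidParameterError,
)

logger = logging.getLogger(__name__)

#: closeness to B0 = 2 at which the closed forms are refused
B0_SINGULARITY_TOL = 1e-6


def _require_positive(name: str, value: float) -> None:
    if not math.isfinite(value) or value <= 0:
        raise InvalidParameterError(f"{name} must be finite and > 0, got {value!r}")


def _require_nonnegative(name: str, value: float) -> None:
    if not math.isfinite(value) or value < 0:
        raise InvalidParameterError(f"{name} must be finite and >= 0, got {value!r}")


@dataclass(frozen=True)
class PhysicalParameters:
    """Dimensional operating parameters of the hollow-fiber DKR reactor.

    Concentrations are in mM, radii in cm, rates in mM/h (the customary
    bench units), diffusivity in cm^2/min. Rates are converted to a
    per-minute basis internally before any dimensionless group is formed.

    Attributes
    ----------
    s_OH : base (NaOH) concentration driving racemization, mM
    s_T0 : initial racemic substrate concentration, mM (defaults to 2*s_B0)
    s_A0, s_B0 : initial (S)- and (R)-ester concentrations, mM
    s_I : non-competitive inhibitor (alcohol by-product) concentration, mM
    K_rac : racemization rate constant, mM/h per mM base
    K_mA, K_mB : Michaelis-Menten constants, mM
    v_max : maximum hydrolysis rate, mM/h
    K_uS1, K_uS1_prime : uncompetitive substrate-inhibition constants, mM
    K_nI1 : non-competitive inhibition constant, mM
    D_eff : effective diffusivity, cm^2/min
    a, c : inner and outer fiber wall radii, cm
    L : effective fiber length, cm
    N : number of fibers
    alpha_p : membrane porosity (0, 1]
    F : volumetric flow rate, cm^3/min
    """

    s_OH: float
    s_A0: float
    s_B0: float
    s_I: float
    K_rac: float
    K_mA: float
    v_max: float
    K_uS1: float
    K_nI1: float
    D_eff: float
    a: float
    c: float
    L: float
    N: int
    alpha_p: float
    F: float
    s_T0: float | None = None
    K_mB: float | None = None
    K_uS1_prime: float | None = None

    def __post_init__(self) -> None:
        for name in ("s_OH", "s_A0", "s_B0", "s_I", "K_rac"):
            _require_nonnegative(name, getattr(self, name))
        for name in ("K_mA", "v_max", "K_uS1", "K_nI1", "D_eff", "a", "c", "L", "F"):
            _require_positive(name, getattr(self, name))
        for name in ("s_T0", "K_mB", "K_uS1_prime"):
            value = getattr(self, name)
            if value is not None:
                _require_positive(name, value)
        if int(self.N) != self.N or self.N < 1:
            raise InvalidParameterError(f"N must be an integer >= 1, got {self.N!r}")
        if not 0 < self.alpha_p <= 1:
            raise InvalidParameterError(
                f"alpha_p must be in (0, 1], got {self.alpha_p!r}"
            )
        if self.c <= self.a:
            raise InvalidParameterError(
                f"outer radius c={self.c!r} must exceed inner radius a={self.a!r}"
            )
        if abs(self.c / self.a - 2.0) > 1e-9:
            # the closed forms and the x in [1, 2] domain assume c/a = 2
            warnings.warn(
                f"c/a = {self.c / self.a:.6g}; the model domain assumes c/a = 2",
                stacklevel=2,
            )


@dataclass(frozen=True)
class DimensionlessParameters:
    """The seven dimensionless groups governing the steady-state system.

    phi2      Thiele modulus squared, a^2 * alpha_p * v_max / (D_eff * K_mA);
              reaction rate relative to radial diffusion.
    b0        Bodenstein number, r*u(r)/D_eff = F / (2*pi*L*N*D_eff);
              convective momentum transfer relative to molecular diffusion.
    theta     Michaelis-Menten group K_mA / s_A0.
    gamma     racemization group a^2 * r_rac / (D_eff * s_T0).
    xi1       substrate-inhibition group s_B0 / K_uS1 ((R)-ester inhibition).
    xi2       by-product inhibition group s_A0 / K_nI1.
    phi_frac  molar fraction of the alcohol by-product, s_I / s_A0.
    """

    phi2: float
    b0: float
    theta: float
    gamma: float = 0.0
    xi1: float = 0.0
    xi2: float = 0.0
    phi_frac: float = 0.0

    def __post_init__(self) -> None:
        for name in ("phi2", "gamma", "xi1", "xi2", "phi_frac"):
            _require_nonnegative(name, getattr(self, name))
        for name in ("b0", "theta"):
            _require_positive(name, getattr(self, name))

    def require_regular_b0(self) -> None:
        """Refuse B0 within 1e-6 of 2 (closed-form denominators contain B0 - 2)."""
        from .exceptions import SingularParameterError

        if abs(self.b0 - 2.0) < B0_SINGULARITY_TOL:
            raise SingularParameterError(
                f"b0 = {self.b0!r} is within {B0_SINGULARITY_TOL} of the removable "
                "singularity at b0 = 2; the closed forms are not evaluated there"
            )

    def replace(self, **changes: float) -> "DimensionlessParameters":
        kwargs = {f.name: getattr(self, f.name) for f in fields(self)}
        kwargs.update(changes)
        return DimensionlessParameters(**kwargs)


@dataclass(frozen=True)
class BulkState:
    """Bulk-phase state: dimensionless bulk concentrations and conversion.

    s1b, s2b are the bulk (S)- and (R)-ester concentrations relative to their
    initial values; x_conv is the conversion degree X = (S1b - S1)/S1b. The
    conversion-degree closed forms carry factors of (X - 1), so X must stay
    strictly below 1.
    """

    s1b: float = 1.0
    s2b: float = 1.0
    x_conv: float = 0.0

    def __post_init__(self) -> None:
        _require_positive("s1b", self.s1b)
        _require_positive("s2b", self.s2b)
        if not math.isfinite(self.x_conv) or not 0 <= self.x_conv < 1:
            raise InvalidParameterError(
                f"x_conv must lie in [0, 1), got {self.x_conv!r}"
            )


def to_dimensionless(phys: PhysicalParameters) -> DimensionlessParameters:
    """Map dimensional reactor parameters onto the dimensionless groups.

    Rates quoted in mM/h (v_max, K_rac) are converted to mM/min so every
    group is formed on a single time base consistent with D_eff in cm^2/min.
    The Bodenstein number uses u(r) = F / (2*pi*r*L*N), in which the radius
    cancels: B0 = F / (2*pi*L*N*D_eff) is constant across the annulus.
    When s_T0 is not supplied it defaults to 2*s_B0 (a racemic feed).
    """
    v_max_min = phys.v_max / 60.0
    r_rac_min = phys.K_rac * phys.s_OH / 60.0
    s_T0 = phys.s_T0 if phys.s_T0 is not None else 2.0 * phys.s_B0
    _require_positive("s_T0", s_T0)
    _require_positive("s_A0", phys.s_A0)

    p = DimensionlessParameters(
        phi2=phys.a**2 * phys.alpha_p * v_max_min / (phys.D_eff * phys.K_mA),
        b0=phys.F / (2.0 * math.pi * phys.L * phys.N * phys.D_eff),
        theta=phys.K_mA / phys.s_A0,
        gamma=phys.a**2 * r_rac_min / (phys.D_eff * s_T0),
        xi1=phys.s_B0 / phys.K_uS1,
        xi2=phys.s_A0 / phys.K_nI1,
        phi_frac=phys.s_I / phys.s_A0,
    )
    logger.debug("derived dimensionless groups: %s", p)
    return p


def reaction_rate_s1(s1, s2, p: DimensionlessParameters):
    """Dimensionless hydrolysis rate of the (S)-ester.

    Phi^2 * S1 / ((1 + S1/Theta)(1 + phi*xi2 + xi1*S2)): Michaelis-Menten in
    S1 with multiplicative non-competitive (alcohol, phi*xi2) and
    uncompetitive ((R)-ester, xi1*S2) inhibition. Accepts scalars or arrays.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    if np.any(s1 < 0) or np.any(s2 < 0):
        raise DegenerateStateError("reaction rate requires s1 >= 0 and s2 >= 0")
    out = p.phi2 * s1 / ((1.0 + s1 / p.theta) * (1.0 + p.phi_frac * p.xi2 + p.xi1 * s2))
    return out if out.ndim else float(out)


def racemization_rate(s1, s2, gamma: float):
    """Dimensionless racemization source gamma * (S1 - S2)/(S1 + S2).

    Antisymmetric under swapping the enantiomers; zero for a racemic mixture.
    """
    s1 = np.asarray(s1, dtype=float)
    s2 = np.asarray(s2, dtype=float)
    total = s1 + s2
    if np.any(total <= 0):
        raise DegenerateStateError("racemization rate requires s1 + s2 > 0")
    out = gamma * (s1 - s2) / total
    return out if out.ndim else float(out)


def _check_domain(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0 - 1e-12) or np.any(x > 2.0 + 1e-12):
        raise DomainError(f"radial coordinate must lie in [1, 2], got {x!r}")
    return x


def ode_residual(x, s, ds, d2s, p: DimensionlessParameters):
    """Residuals of the governing system at radius x.

    Parameters are the state pair ``s = (s1, s2)``, first derivatives ``ds``
    and second derivatives ``d2s`` (each scalar or array-valued). Both
    components vanish iff the triple satisfies the governing ODEs at x.
    """
    x = _check_domain(x)
    s1, s2 = s
    ds1, ds2 = ds
    d2s1, d2s2 = d2s
    conv = (1.0 + p.b0) / x
    r1 = np.asarray(d2s1) + conv * np.asarray(ds1) - reaction_rate_s1(s1, s2, p)
    r2 = np.asarray(d2s2) + conv * np.asarray(ds2) - racemization_rate(s1, s2, p.gamma)
    if r1.ndim == 0:
        return float(r1), float(r2)
    return r1, r2


def boundary_residual(s_at_1, ds_at_1, s_at_2):
    """Residuals of the four boundary conditions.

    Returns (S1'(1), S2'(1), S1(2) - 1, S2(2) - 1); all zero iff the no-flux
    inner condition and the bulk outer condition hold.
    """
    ds1_1, ds2_1 = ds_at_1
    s1_2, s2_2 = s_at_2
    return float(ds1_1), float(ds2_1), float(s1_2) - 1.0, float(s2_2) - 1.0


def robin_wall_profile(x, b0: float):
    """Wall profile 1 - x**(-B0) implied by the convective outer condition.

    Solves dS/dx = (B0/x)(1 - S) with S(1) = 0. At x = 2 the profile reaches
    1 - 2**(-B0), which is within 0.25% of 1 for B0 >= 8.68 and justifies the
    Dirichlet approximation S(2) = 1 used by the model.
    """
    if b0 <= 0:
        raise InvalidParameterError(f"b0 must be > 0, got {b0!r}")
    x = np.asarray(x, dtype=float)
    if np.any(x < 1.0):
        raise DomainError("wall profile defined for x >= 1")
    out = 1.0 - np.exp(-b0 * np.log(x))
    return out if out.ndim else float(out)
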