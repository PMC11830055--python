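"""Exception hierarchy used across the package."""


class DkrError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(DkrError, ValueError):
    """A parameter violates its physical or mathematical constraint."""


class SingularParameterError(InvalidParameterError):
    """Parameter combination hits a removable singularity of a closed form.

    The second-order series solutions carry factors of (B0 - 2) in their
    denominators, so Bodenstein numbers within 1e-6 of 2 are rejected rather
    than evaluated through the analytic limit.
    """


class DomainError(DkrError, ValueError):
    """A coordinate falls outside the dimensionless annulus [1, 2]."""


class DegenerateStateError(DkrError, ValueError):
    """A state that makes a rate expression undefined, e.g. S1 + S2 <= 0."""


class ConvergenceError(DkrError, RuntimeError):
    """The collocation solver failed to reach the requested tolerance."""

    def __init__(self, message: str, achieved_residual: float | None = None):
        super().__init__(message)
        self.achieved_residual = achieved_residual


class NoBoundaryError(DkrError, ValueError):
    """A validity map contains no frontier (all cells valid or all invalid)."""


class ConfigurationError(DkrError, ValueError):
    """Malformed configuration text, unknown key, or invariant violation."""
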