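"""Exception hierarchy.

Estimation methods signal "I do not apply to this series" with specific
exceptions so the method cascade can record the reason and fall through to
the next method instead of aborting.
"""


class DhbPkaError(Exception):
    """Base class for all package errors."""


class InvalidSystemError(DhbPkaError, ValueError):
    """Acid system violates its invariants (e.g. non-increasing pKa list)."""


class ConfigurationError(DhbPkaError, ValueError):
    """Inconsistent simulation or analysis configuration."""


class ParameterError(DhbPkaError, ValueError):
    """Numerical parameter outside its valid range (e.g. SG window)."""


class MethodFailure(DhbPkaError):
    """A pKa estimation method does not apply to the given data.

    Caught by the cascade; the message becomes the recorded skip reason.
    """


class NoCrossingError(MethodFailure):
    """Two absorbance-vs-pH traces never intersect in the pH range."""


class DegenerateSeriesError(MethodFailure):
    """Series carries no pH-dependent signal (single species, flat data)."""


class MethodInapplicableError(MethodFailure):
    """Preconditions of a method are not met by this series."""


class InsufficientDataError(MethodFailure):
    """Too few usable points to fit."""


class NoTransitionError(MethodFailure):
    """Absorbances show no dissociation transition (e.g. A1 = A2 = A3)."""


class IllConditionedError(MethodFailure):
    """Closed-form expression numerically degenerate for these inputs."""


class UnresolvedDissociationError(DhbPkaError):
    """Every cascade method failed for one dissociation step."""

    def __init__(self, step: int, reasons: dict[str, str]):
        self.step = step
        self.reasons = dict(reasons)
        detail = "; ".join(f"{m}: {r}" for m, r in reasons.items())
        super().__init__(f"dissociation step {step}: all methods failed ({detail})")


class PairingError(DhbPkaError, ValueError):
    """Experimental/computed pKa pairing impossible (one side empty)."""


class AlignmentError(DhbPkaError, ValueError):
    """Compound sets of two tables being compared do not match."""
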