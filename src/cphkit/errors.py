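"""Exception hierarchy for cphkit."""


class CphkitError(Exception):
    """Base class for all package-specific errors."""


class InvalidModelError(CphkitError):
    """A model object contains non-finite or inconsistent parameters."""


class MissingDataError(CphkitError):
    """Required samples or file content are absent."""


class UnderdeterminedFitError(CphkitError):
    """Polynomial fit order too high for the number of grid points."""


class UndefinedFractionError(CphkitError):
    """No classifiable frames: the deprotonation fraction is undefined."""


class NonIdentifiableError(CphkitError):
    """Titration data cannot identify a pKa (all fractions 0 or 1)."""


class IntegrationBlowupError(CphkitError):
    """A toy-dynamics trajectory diverged."""

    def __init__(self, step: int, value: float, message: str = ""):
        self.step = step
        self.value = value
        super().__init__(
            message or f"integration blew up at step {step} (coordinate {value:g})"
        )


class DisconnectedHistogramError(CphkitError):
    """Umbrella windows do not overlap; WHAM cannot connect them."""


class AlignmentUndefinedError(CphkitError):
    """Torsion correction phase alignment undefined (flat base profile)."""


class SeedCollisionError(CphkitError):
    """Two replicas were given identical random seeds."""


class ParseError(CphkitError):
    """Malformed text input (xvg/CSV)."""
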