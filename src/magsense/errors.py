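"""Exception hierarchy used across the package."""


class MagsenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(MagsenseError, ValueError):
    """An argument is outside the physically meaningful domain."""


class SingularityError(MagsenseError, ValueError):
    """Two particles coincide; dipolar quantities are singular."""


class PlacementError(MagsenseError, RuntimeError):
    """Random ensemble generation could not place all particles."""


class ParseError(MagsenseError, ValueError):
    """A particle table or trajectory file could not be parsed."""


class IntegrationError(MagsenseError, RuntimeError):
    """A dynamics integration became unstable or diverged."""


class StabilityError(MagsenseError, RuntimeError):
    """A transport/MD step violated its stability constraint."""


class ConfigError(MagsenseError, ValueError):
    """A run configuration file is invalid."""


class FitError(MagsenseError, RuntimeError):
    """A parameter fit failed or is not identifiable."""


class NoDecayError(FitError):
    """The dissociation-phase fit found no decaying signal."""


class NonIdentifiableError(FitError):
    """The data cannot constrain the requested parameters."""
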