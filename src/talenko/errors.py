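"""Exception hierarchy for talenko.

Every error raised on bad user input derives from TalenkoError so the CLI can
map them onto its exit-code contract (2 = configuration, 3 = stage failure).
"""


class TalenkoError(Exception):
    """Base class for all talenko errors."""


class ParameterError(TalenkoError, ValueError):
    """A parameter value is out of its documented domain."""


class ContradictionError(ParameterError):
    """Mutually inconsistent simulation parameters (e.g. identity floor 1.0
    together with a positive number of divergent sites)."""


class NoCutSiteError(TalenkoError):
    """A TALEN pair has no binding site in any gene copy."""


class PedigreeError(TalenkoError):
    """Impossible cross or transmission request."""


class EncodingError(TalenkoError, ValueError):
    """Invalid base or RVD in the TAL cipher."""


class CoordinateSystemError(TalenkoError):
    """Variant sets declared in different coordinate systems; no silent
    lift-over is attempted."""


class GenotypeParseError(TalenkoError, ValueError):
    """Malformed founder genotype token."""


class NoJunctionError(TalenkoError):
    """An amplicon cannot be decomposed into an A-prefix / B-suffix chimera
    with the requested anchors."""


class ConfigError(TalenkoError):
    """Invalid or unknown pipeline configuration key/value."""


class StageError(TalenkoError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
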