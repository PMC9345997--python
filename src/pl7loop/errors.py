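"""Exception hierarchy for the PL7 loop-annotation pipeline."""


class Pl7LoopError(Exception):
    """Base class for all package errors."""


class FormatError(Pl7LoopError):
    """A file could not be parsed in the expected dialect."""


class ValidationError(Pl7LoopError):
    """Parsed content violates a domain invariant (e.g. illegal residue)."""


class AnchorNotFoundError(Pl7LoopError):
    """No QI(V)H match anywhere in the sequence; the topology walk cannot start."""


class CenterStrandNotFoundError(Pl7LoopError):
    """The QI(V)H anchor does not sit on any beta-strand segment (SS/motif disagreement)."""


class LoopNotFoundError(Pl7LoopError):
    """The expected loop run is missing from the strand/loop topology."""


class ProjectionFailedError(Pl7LoopError):
    """A template span fell entirely inside an alignment gap and cannot be projected."""


class AnnotationFailedError(Pl7LoopError):
    """Both loop-location strategies failed for a record.

    Carries the underlying causes so batch callers can report them.
    """

    def __init__(self, message: str, causes: list[Exception] | None = None):
        super().__init__(message)
        self.causes = causes or []


class PairingError(Pl7LoopError):
    """Prediction/observation ids could not be matched one-to-one."""

    def __init__(self, message: str, offenders: list[str] | None = None):
        super().__init__(message)
        self.offenders = offenders or []


class ChimeraConstructionError(Pl7LoopError):
    """Loop spans passed to the chimera builder are out of range or overlap."""
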