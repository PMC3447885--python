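"""Exception hierarchy shared across the toolkit."""


class ZinclusterError(Exception):
    """Base class for all toolkit errors."""


class InvalidPeakError(ZinclusterError, ValueError):
    """A mass peak with non-positive m/z or charge."""


class SequenceParseError(ZinclusterError, ValueError):
    """An amino-acid sequence containing a non-canonical letter."""

    def __init__(self, message: str, position: int | None = None):
        super().__init__(message)
        self.position = position


class InfeasibleConnectivityError(ZinclusterError, ValueError):
    """Connectivity input that violates a hard constraint; the message names it."""


class MissingScoreError(ZinclusterError, KeyError):
    """A candidate assignment was not given a violation score."""


class EmptyOverlapError(ZinclusterError, ValueError):
    """Two tables share no (residue, nucleus) keys."""


class PatternError(ZinclusterError, ValueError):
    """A malformed motif pattern; carries the character offset."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class DegenerateGeometryError(ZinclusterError, ValueError):
    """A superposition pairing that is collinear or otherwise ill-conditioned."""


class AtomLookupError(ZinclusterError, LookupError):
    """A named atom is absent from a model; the message names it."""


class GenerationError(ZinclusterError, ValueError):
    """A synthetic-data template that cannot be realized."""
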