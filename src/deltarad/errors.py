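"""Exception hierarchy for the delta-radiomics pipeline."""


class DeltaRadError(Exception):
    """Base class for all package errors."""


class FormatError(DeltaRadError):
    """A volume file could not be read or its header is ambiguous."""


class DimensionalityError(FormatError):
    """The image payload is not a 3D scalar grid."""


class GeometryError(DeltaRadError):
    """Volume/mask geometry mismatch or lesion exceeding the grid."""


class DegenerateLesionError(DeltaRadError):
    """The lesion mask is empty or collapses under an operation."""


class MarginUndefinedError(DeltaRadError):
    """No usable surface sampling line could be fitted."""


class ClassError(DeltaRadError):
    """A binary-label operation received a single class."""


class PairingError(DeltaRadError):
    """Test/retest columns cannot be paired."""


class AlignmentError(DeltaRadError):
    """Feature tables cannot be aligned by subject or column."""


class ParameterError(DeltaRadError):
    """An operation parameter violates its precondition."""


class StageError(DeltaRadError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
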