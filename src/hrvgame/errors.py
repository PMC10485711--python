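"""Exception hierarchy shared by all hrvgame modules."""


class HRVGameError(Exception):
    """Base class for all package-specific errors."""


class ParseError(HRVGameError):
    """A recording file contains a line that cannot be parsed."""


class ValidationError(HRVGameError):
    """A value violates a domain invariant (e.g. non-positive RR interval)."""


class EmptyInputError(HRVGameError):
    """An operation received an empty recording or stream."""


class InsufficientDataError(HRVGameError):
    """Too few beats / too short a recording for the requested analysis."""


class UnusableRecordingError(HRVGameError):
    """Artifact filtering rejected too large a fraction of beats."""


class LevelTooShortError(HRVGameError):
    """A prerecorded series is too short to build a level from."""


class PathologicalParametersError(HRVGameError):
    """Simulator parameters would produce physiologically impossible beats."""


class StateMachineError(HRVGameError):
    """A game-state transition was requested from a terminal state."""


class IncompletePhaseError(HRVGameError):
    """A participant is missing games for a study phase."""


class EmptyGroupError(HRVGameError):
    """A study group contains no participants."""


class SchemaValidationError(HRVGameError):
    """A session document violates the (anonymized) schema."""


class SchemaVersionError(HRVGameError):
    """A session document carries an unknown schema version."""


class CalibrationMismatchWarning(UserWarning):
    """Reference-curve values map far outside the calibrated screen span."""
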