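"""Exception types shared across the package."""


class GaitIntentError(Exception):
    """Base class for package-specific errors."""


class DegenerateGeometryError(GaitIntentError, ValueError):
    """A geometric primitive collapsed (zero vector, coincident points)."""


class InsufficientDataError(GaitIntentError, ValueError):
    """Too little data for the requested operation."""


class UnresolvedPhaseError(GaitIntentError, ValueError):
    """Gait phase cannot be determined at the start of a stream."""


class IllConditionedModelError(GaitIntentError, ValueError):
    """A regularized covariance is numerically singular."""


class ModelFormatError(GaitIntentError, ValueError):
    """A stored model file is corrupted or has an unsupported version."""


class InvalidProtocolError(GaitIntentError, ValueError):
    """A treadmill protocol is internally inconsistent."""
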