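"""Exception types shared across the package."""


class GazeMetricsError(Exception):
    """Base class for all package-specific errors."""


class InputError(GazeMetricsError, ValueError):
    """Unusable input (empty file, no samples, mismatched ids)."""


class FormatError(GazeMetricsError, ValueError):
    """A file or record violates the documented format or its invariants."""


class ClassificationError(GazeMetricsError, ValueError):
    """The stream cannot be classified (fewer than two samples)."""


class UndefinedGazeIndexError(GazeMetricsError, ValueError):
    """The Gaze Index is undefined (zero scanning time or empty sequence)."""
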