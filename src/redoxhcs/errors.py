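"""Exception hierarchy for redoxhcs.

All package errors derive from :class:`RedoxHCSError` so callers (and the
CLI) can map failure categories to exit codes without string matching.
"""


class RedoxHCSError(Exception):
    """Base class for all redoxhcs errors."""


class ValidationError(RedoxHCSError, ValueError):
    """A parameter object or input violates its documented invariants."""


class PlacementError(ValidationError):
    """The requested number of cells cannot be placed at the given spacing."""


class FormatError(RedoxHCSError, ValueError):
    """On-disk data violates the documented file/naming conventions."""


class ConfigurationError(RedoxHCSError, ValueError):
    """A run configuration or plate layout is unusable (e.g. no controls)."""


class UndefinedSeparationError(RedoxHCSError, ValueError):
    """Z' is undefined because the control arms have identical means."""


class UndefinedCorrelationError(RedoxHCSError, ValueError):
    """Correlation is undefined (zero variance in one of the inputs)."""
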