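"""Exception hierarchy shared across the package."""


class VpetypesError(Exception):
    """Base class for all package-specific errors."""


class FormatError(VpetypesError):
    """A session bundle on disk does not match the expected file layout."""


class ValidationError(VpetypesError):
    """In-memory session data violates a type invariant.

    Carries the full list of violation strings so callers can report all
    problems at once.
    """

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class ParameterError(VpetypesError, ValueError):
    """An analysis parameter is outside its valid range."""


class InsufficientDataError(VpetypesError):
    """Too few trials/spikes/subjects for the requested statistic."""


class DegenerateDataError(VpetypesError):
    """Data are degenerate for the requested operation (e.g. zero baseline SD,
    an empty group in a contingency table)."""


class UndefinedResultError(VpetypesError):
    """The requested quantity is undefined for this input (e.g. rhythm
    frequency of a non-rhythmic unit)."""


class ConfigError(VpetypesError, ValueError):
    """A simulator configuration value is invalid."""
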