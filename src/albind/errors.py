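"""Exception hierarchy shared across the package."""


class AlbindError(Exception):
    """Base class for all package errors."""


class FormatError(AlbindError):
    """A file does not conform to the expected delimited-text layout."""


class ValidationError(AlbindError):
    """An input value violates a physical or structural precondition."""


class FitError(AlbindError):
    """A regression could not be performed (too few points, degenerate data)."""


class AnalysisError(AlbindError):
    """A downstream analysis step found nothing to work with."""


class ConfigError(AlbindError):
    """A scenario or run configuration is inconsistent."""
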