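"""Exception hierarchy shared across the package."""


class PolwaveError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(PolwaveError):
    """Invalid configuration value or combination."""


class ParseError(PolwaveError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class DataError(PolwaveError):
    """Inconsistent or incomplete input data (missing samples, truth records, ...)."""


class BoundsError(PolwaveError):
    """A requested genomic window falls outside the contig."""


class NormalizationError(PolwaveError):
    """Spike-in or density normalization cannot be computed."""


class FitError(PolwaveError):
    """A model fit is impossible on the given input."""


class ComparisonError(PolwaveError):
    """Two result sets cannot be compared (e.g. disjoint gene universes)."""
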