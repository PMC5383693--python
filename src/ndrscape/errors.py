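"""Exception hierarchy shared across the package."""


class NdrscapeError(Exception):
    """Base class for all errors raised by this package."""


class ParseError(NdrscapeError):
    """A file could not be parsed; carries the path and 1-based line number."""

    def __init__(self, path, lineno, message):
        self.path = str(path)
        self.lineno = lineno
        super().__init__(f"{self.path}:{lineno}: {message}")


class SchemaError(NdrscapeError):
    """A tabular input is missing required columns or has wrong types."""


class ValidationError(NdrscapeError):
    """A parsed record violates a type invariant."""


class CapacityError(NdrscapeError):
    """Requested simulation does not fit on the chromosome."""


class ConfigError(NdrscapeError):
    """A run configuration is malformed."""


class WindowOutOfBounds(NdrscapeError):
    """Signal: a TSS-centered window extends past the chromosome.

    Callers catch this to drop the gene (and count it) rather than abort.
    """
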