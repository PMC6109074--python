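"""Exception hierarchy.

Everything raised on bad user input derives from :class:`PermdegError` so
callers (and the CLI) can catch one type; most also derive from the matching
builtin so idiomatic ``except ValueError`` still works.
"""


class PermdegError(Exception):
    """Base class for all errors raised by permdeg."""


class ValidationError(PermdegError, ValueError):
    """Malformed or inconsistent input data (ids, shapes, value ranges)."""


class ConfigurationError(PermdegError, ValueError):
    """Invalid simulation or run configuration."""


class DesignError(PermdegError, ValueError):
    """Experimental design unusable for the requested analysis
    (e.g. a group with fewer than two replicates)."""


class NormalizationError(PermdegError, ValueError):
    """Scaling factors cannot be computed (e.g. an all-zero sample)."""


class ParseError(PermdegError, ValueError):
    """A text input file could not be parsed; carries the line number."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        super().__init__(f"{loc}: {message}" if loc else message)
        self.path = path
        self.line = line


class PipelineError(PermdegError, RuntimeError):
    """A pipeline stage failed; message is prefixed with the stage name."""
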