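"""Exception hierarchy shared by all driveways modules.

The CLI maps these onto its exit-code contract: configuration problems
exit 1, data/format problems exit 2, solver infeasibility exits 3.
"""


class DriveWaysError(Exception):
    """Base class for all errors raised by this package."""


class ConfigurationError(DriveWaysError):
    """Invalid parameter combination or option usage."""


class ParseError(DriveWaysError):
    """Malformed input data; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        loc = ""
        if path is not None:
            loc += f"{path}"
        if line is not None:
            loc += f":{line}"
        if loc:
            message = f"{loc}: {message}"
        super().__init__(message)
        self.path = path
        self.line = line


class InfeasibleError(DriveWaysError):
    """A size-constrained instance admits no feasible solution."""


class ResourceLimitError(DriveWaysError):
    """An enumeration exceeded its configured cap; use a smaller instance."""
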