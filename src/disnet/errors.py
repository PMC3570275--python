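"""Exception hierarchy shared across the toolkit.

The CLI maps :class:`DisnetError` subclasses onto its exit-code contract:
configuration/argument problems exit 2, input-data problems exit 1.
"""


class DisnetError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(DisnetError):
    """A dialect, column mapping, or option is inconsistent with the input."""


class InputError(DisnetError):
    """Malformed input data; carries file/line context when known."""

    def __init__(self, message: str, path: str | None = None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix = f"{path}:"
            if line is not None:
                prefix += f"{line}:"
            prefix += " "
        super().__init__(prefix + message)


class LookupFailure(DisnetError):
    """An identifier could not be resolved against a graph."""


class AmbiguousIdentifier(LookupFailure):
    """A symbol matched several distinct nodes."""

    def __init__(self, identifier: str, candidates: list[str]):
        self.identifier = identifier
        self.candidates = candidates
        super().__init__(
            f"identifier {identifier!r} is ambiguous; candidates: {', '.join(sorted(candidates))}"
        )


class RuleParseError(DisnetError):
    """Boolean rule text failed to parse; reports line and column."""

    def __init__(self, message: str, line: int, column: int):
        self.line = line
        self.column = column
        super().__init__(f"line {line}, column {column}: {message}")


class RuleStructureError(DisnetError):
    """Rule set parsed but violates structural constraints (missing/duplicate/out-of-range nodes)."""


class ModeError(DisnetError):
    """A network was used with the wrong update semantics."""


class ResourceLimitError(DisnetError):
    """A computation would exceed a configured cap (e.g. state-space enumeration)."""
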