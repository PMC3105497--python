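"""Exception types shared across the package."""


class FlowsynthError(Exception):
    """Base class for all package-specific errors."""


class UnknownNameError(FlowsynthError, KeyError):
    """A symbolic name is not known to a taxonomy or domain.

    Carries the offending symbol and, where available, a short list of
    near-miss suggestions for error messages.
    """

    def __init__(self, name: str, context: str = "", suggestions: tuple[str, ...] = ()):
        self.name = name
        self.suggestions = tuple(suggestions)
        msg = f"unknown name {name!r}"
        if context:
            msg += f" ({context})"
        if suggestions:
            msg += "; did you mean: " + ", ".join(suggestions)
        super().__init__(msg)

    def __str__(self) -> str:  # KeyError would repr() the args tuple
        return self.args[0]


class ContractViolation(FlowsynthError):
    """An operation was invoked outside its precondition."""


class ParseError(FlowsynthError):
    """Malformed input text; carries a 1-based line (and column when known)."""

    def __init__(self, message: str, line: int | None = None, column: int | None = None):
        self.line = line
        self.column = column
        parts = []
        if line is not None:
            parts.append(f"line {line}")
        if column is not None:
            parts.append(f"column {column}")
        loc = f" at {', '.join(parts)}" if parts else ""
        super().__init__(message + loc)
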