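"""Exception hierarchy.

``ProtfunError`` marks user-facing input problems (bad files, unknown
identifiers, invalid parameter values); anything else escaping the library
is treated as an internal error by the CLI.
"""


class ProtfunError(Exception):
    """Base class for user-facing errors."""


class FormatError(ProtfunError):
    """A file does not conform to its declared format.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class CycleError(ProtfunError):
    """The ontology's directed parent relation contains a cycle."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(
            "ontology parent relation is cyclic: " + " -> ".join(self.cycle)
        )


class UnknownClassError(ProtfunError, KeyError):
    """A class identifier cannot be resolved in the ontology."""

    def __init__(self, identifier: str, context: str = ""):
        self.identifier = identifier
        msg = f"unknown ontology class {identifier!r}"
        if context:
            msg += f" ({context})"
        ProtfunError.__init__(self, msg)

    def __str__(self) -> str:  # KeyError quotes its arg; keep the message
        return self.args[0]
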