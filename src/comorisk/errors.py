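"""Exception hierarchy shared by all comorisk modules."""


class ComoriskError(Exception):
    """Base class for all package errors."""


class ParseError(ComoriskError):
    """A file could not be parsed; carries the offending line number when known."""

    def __init__(self, message: str, path=None, line: int | None = None):
        self.path = path
        self.line = line
        prefix = ""
        if path is not None:
            prefix += f"{path}"
        if line is not None:
            prefix += f":{line}"
        super().__init__(f"{prefix}: {message}" if prefix else message)


class ValidationError(ComoriskError):
    """An input value violates a documented invariant."""


class DomainError(ComoriskError):
    """An operation was called outside its mathematical domain."""


class DegenerateStatisticError(DomainError):
    """A statistic is undefined for these counts (zero/negative denominator
    or radicand).  ``sentinel`` carries the conventional replacement value
    (e.g. +inf for a relative risk whose denominator collapses to zero)."""

    def __init__(self, message: str, sentinel: float = float("inf")):
        self.sentinel = sentinel
        super().__init__(message)


class UndefinedConfidenceIntervalError(DomainError):
    """Katz interval requested where sigma is undefined (C_ij = 0)."""


class CycleError(ValidationError):
    """An ontology input contains a cycle; carries one witness cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__(f"ontology is not acyclic; witness cycle: {' -> '.join(map(str, self.cycle))}")


class LookupError_(ComoriskError, KeyError):
    """An identifier could not be resolved; may carry close matches."""

    def __init__(self, message: str, suggestions=()):
        self.suggestions = list(suggestions)
        if self.suggestions:
            message += f" (closest matches: {', '.join(self.suggestions)})"
        super().__init__(message)

    def __str__(self):  # KeyError quotes its arg; keep the plain message
        return self.args[0]
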