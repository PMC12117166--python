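"""Exception hierarchy shared across the package."""

from __future__ import annotations


class PathoGraphError(Exception):
    """Base class for all package-specific errors."""


class ResolutionError(PathoGraphError):
    """An identifier reference could not be resolved."""

    def __init__(self, ref: str, context: str = ""):
        self.ref = ref
        msg = f"unresolved reference {ref!r}"
        if context:
            msg += f" ({context})"
        super().__init__(msg)


class CycleError(PathoGraphError):
    """A relation that must be acyclic contains a cycle."""

    def __init__(self, cycle):
        self.cycle = list(cycle)
        super().__init__("cycle detected: " + " -> ".join(self.cycle))


class GeometryError(PathoGraphError):
    """Invalid or degenerate polygon/arc geometry."""


class DocumentValidationError(PathoGraphError):
    """A document failed validation; carries the violation records."""

    def __init__(self, violations):
        self.violations = list(violations)
        lines = "; ".join(str(v) for v in self.violations[:5])
        super().__init__(f"{len(self.violations)} validation violation(s): {lines}")


class PathoMLParseError(PathoGraphError):
    """Input text could not be interpreted as a PathoML document."""


class AmbiguityError(PathoGraphError):
    """A query produced conflicting values for the same individual."""


class EmptyCohortError(PathoGraphError):
    """A staining distribution was requested for zero cells."""
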