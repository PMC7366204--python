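"""Exception hierarchy for cohortforge."""


class CohortForgeError(Exception):
    """Base class for all cohortforge errors."""


class FactValidationError(CohortForgeError):
    """An observation fact violates its invariants.

    Carries the offending field name and, when raised during a batch
    operation, the zero-based row index within the batch.
    """

    def __init__(self, field: str, message: str, row: int | None = None):
        self.field = field
        self.row = row
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(f"{prefix}{field}: {message}")


class NotFoundError(CohortForgeError):
    """A referenced entity (patient, node, logic, run) does not exist."""


class ConfigurationError(CohortForgeError):
    """A definition references missing columns, bad operators, etc."""


class LoadError(CohortForgeError):
    """A flat file (TSV hierarchy, cdi file) is malformed."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MappingError(CohortForgeError):
    """A local-to-standard code mapping cannot be applied."""


class EvaluationError(CohortForgeError):
    """A cohort query cannot be evaluated (unresolvable concept, etc.)."""


class CycleError(CohortForgeError):
    """Derived-concept definitions form a circular dependency."""

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        chain = " -> ".join(self.cycle + self.cycle[:1])
        super().__init__(f"circular derived-concept dependency: {chain}")


class ExportError(CohortForgeError):
    """Flow-diagram export was given inconsistent inputs."""
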