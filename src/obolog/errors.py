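"""Exception hierarchy shared across the package."""


class OboLogError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(OboLogError):
    """Malformed OBO input (duplicate ids, bad tag syntax, ...)."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class MalformedDefinitionError(OboParseError):
    """A cross-product definition without a genus or without differentia."""


class UnknownEntityError(OboLogError, KeyError):
    """A CURIE or relation id that does not resolve."""


class CycleError(OboLogError):
    """An asserted-edge cycle where a DAG is required."""

    def __init__(self, cycle: list[str], relation: str = "is_a"):
        self.cycle = list(cycle)
        self.relation = relation
        super().__init__(
            f"cycle over {relation}: " + " -> ".join(list(cycle) + [cycle[0]])
        )


class MergeConflictError(OboLogError):
    """Two ontologies assert different content for the same id."""


class InfeasibleParamsError(OboLogError):
    """Random-ontology generator parameters that cannot be satisfied."""


class NotEntailedError(OboLogError):
    """An explanation was requested for an edge that is not entailed."""
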