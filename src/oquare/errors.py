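"""Exception hierarchy shared across the package."""


class OQuaREError(Exception):
    """Base class for all package-specific errors."""


class OntologyParseError(OQuaREError):
    """The input file could not be parsed in the requested dialect."""

    def __init__(self, source: str, dialect: str, cause: str = ""):
        self.source = source
        self.dialect = dialect
        msg = f"could not parse {source!r} as {dialect}"
        if cause:
            msg += f": {cause}"
        super().__init__(msg)


class StructuralError(OQuaREError):
    """The ontology violates a structural invariant (e.g. a subclass cycle)."""

    def __init__(self, message: str, cycle=None):
        self.cycle = list(cycle) if cycle else None
        super().__init__(message)


class PathExplosionError(OQuaREError):
    """The number of leaf-to-root paths exceeds the configured cap."""


class InapplicablePlanError(OQuaREError):
    """A mutation plan cannot be applied to the given ontology graph."""
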