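"""Exception hierarchy.

Everything raised on purpose by this package derives from
:class:`IliacShearError` so callers can catch the package's own failures
without swallowing genuine bugs.
"""


class IliacShearError(Exception):
    """Base class for all errors raised by iliacshear."""


class InvalidParameterError(IliacShearError, ValueError):
    """A scalar argument violates its stated precondition."""


class DomainError(IliacShearError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class ConfigurationError(IliacShearError, ValueError):
    """A patient/cohort configuration is internally inconsistent."""


class ConstitutiveModelError(IliacShearError):
    """Rheology parameters yield a non-monotone stress law (ill-posed solver)."""


class GridTooSmallError(IliacShearError, ValueError):
    """A gridded field has too few nodes for the requested stencil."""


class SolverError(IliacShearError, RuntimeError):
    """A numerical solve failed; the message carries diagnostics."""


class GeometryError(IliacShearError, ValueError):
    """A control volume cannot be fitted into the available vessel."""


class AmbiguousStenosisError(GeometryError):
    """Several disjoint sub-threshold runs exist; the caller must choose."""

    def __init__(self, runs):
        self.runs = list(runs)
        super().__init__(
            f"{len(self.runs)} disjoint sub-threshold runs found: {self.runs}"
        )


class CoverageError(IliacShearError, ValueError):
    """A requested location is outside the stored solution stations."""


class CompletenessError(IliacShearError, ValueError):
    """A statistics table is missing required per-patient entries."""


class IntegrityError(IliacShearError):
    """A bundled read-only fixture failed its checksum."""
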