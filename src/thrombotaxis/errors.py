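"""Exception hierarchy.

All package errors derive from :class:`ThrombotaxisError` so callers can
catch everything with one clause; the subclasses distinguish malformed
files, inconsistent data, bad parameters, out-of-domain queries, solver
failures and synthetic-data generation failures.
"""


class ThrombotaxisError(Exception):
    """Base class for all package errors."""


class FormatError(ThrombotaxisError):
    """A file does not conform to the expected on-disk format."""


class DataError(ThrombotaxisError):
    """Well-formed input whose content violates a data invariant."""


class ParameterError(ThrombotaxisError, ValueError):
    """A physical or numerical parameter is out of its admissible range."""


class DomainError(ThrombotaxisError):
    """A spatial query falls outside the domain it is defined on."""


class NumericalError(ThrombotaxisError):
    """A solver failed to converge or produced an unusable solution."""


class GenerationError(ThrombotaxisError):
    """Synthetic-data generation could not satisfy its constraints."""
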