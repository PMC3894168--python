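"""Exception hierarchy.

All package errors derive from :class:`SnpConsensusError` so callers can
catch one base type; the subclasses mirror the failure domains: malformed
input tables, records violating domain invariants, calibration lookups
outside the fitted domain, and fits on empty/degenerate strata.
"""


class SnpConsensusError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(SnpConsensusError):
    """A file or token does not conform to the expected format."""


class ValidationError(SnpConsensusError):
    """A record violates a domain invariant (e.g. wt == mut residue)."""


class FitError(SnpConsensusError):
    """A calibration fit was attempted on an empty or unusable stratum."""


class CalibrationDomainError(SnpConsensusError):
    """A transform was requested for a (tool, class) or category never fitted."""


class NoPredictionError(SnpConsensusError):
    """Every constituent tool was missing for a mutation."""


class NormalizationError(SnpConsensusError):
    """Confusion-matrix normalization requires both true classes present."""
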