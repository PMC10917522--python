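"""Exception types raised across the package.

All inherit from :class:`BrewtrackError` (itself a ``ValueError``) so callers
can catch everything from one pipeline stage with a single ``except``.
"""


class BrewtrackError(ValueError):
    """Base class for all brewtrack errors."""


class ConfigError(BrewtrackError):
    """Invalid simulation or analysis configuration."""


class InputError(BrewtrackError):
    """Malformed user input (bad residue, p-value outside [0, 1], ...)."""


class IntegrityError(BrewtrackError):
    """Cross-references between tables do not line up (unknown protein,
    evidence peptide absent from its protein, metadata/matrix mismatch)."""


class QuantificationError(BrewtrackError):
    """Quantification cannot proceed (e.g. a sample with zero total signal)."""


class NormalizationError(BrewtrackError):
    """Too few universally detected proteins to anchor between-sample scaling."""


class TransformError(BrewtrackError):
    """Value transform applied to data that does not support it
    (non-positive values before log2, wrong value_kind in the chain)."""


class ProfileError(BrewtrackError):
    """Genome profile cannot be computed (e.g. zero median depth)."""
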