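"""Exception hierarchy for the MR pipeline.

All pipeline errors derive from :class:`MRPipeError` so callers can catch a
single base class; each subclass marks a distinct failure mode named in the
module contracts.
"""


class MRPipeError(Exception):
    """Base class for all mrpipe errors."""


class SchemaError(MRPipeError):
    """A required column is absent or a table cannot be interpreted."""


class HarmonizationError(MRPipeError):
    """Exposure and outcome tables share no variants."""


class ConfigurationError(MRPipeError):
    """An invalid run configuration (missing LD entries, bad thresholds...)."""


class DomainError(MRPipeError, ValueError):
    """An argument outside the mathematical domain of a formula."""


class DegenerateInstrumentError(MRPipeError):
    """An instrument with zero exposure effect cannot form a ratio estimate."""


class InsufficientInstrumentsError(MRPipeError):
    """Fewer instruments than the estimator's minimum."""


class CollinearityError(MRPipeError):
    """Rank-deficient design matrix in a regression-based estimator."""
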