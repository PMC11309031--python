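"""Exception hierarchy for the MR pipeline.

All pipeline-level failures derive from :class:`MRError` so that the
orchestrator can contain per-exposure failures without masking genuine
programming errors.
"""


class MRError(Exception):
    """Base class for analysis-level errors."""


class ConfigurationError(MRError):
    """A config file, column map, or argument combination is unusable."""


class TableValidationError(MRError):
    """A summary-statistics table violates its structural invariants."""


class EmptyInstrumentError(MRError):
    """No instruments survive a selection or harmonization step."""


class InsufficientInstrumentsError(MRError):
    """An estimator needs more instruments than are available."""


class DegenerateInstrumentError(MRError):
    """An instrument with a zero exposure effect cannot form a Wald ratio."""


class DegenerateCorrectionError(MRError):
    """Outlier removal left too few instruments to re-estimate."""
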