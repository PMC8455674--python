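"""Exception hierarchy shared across the package.

Errors are split along the lines a pipeline caller needs to distinguish:
configuration problems (bad column maps, invalid thresholds), input problems
(unreadable or empty tables), and estimation problems (too few instruments,
degenerate data). :class:`PipelineStageError` wraps any of these with the
name of the pipeline stage that raised it.
"""


class MRKitError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MRKitError):
    """A configuration value or column mapping is invalid."""


class InputError(MRKitError):
    """An input file or table is missing, unreadable, or empty."""


class SelectionError(MRKitError):
    """Instrument selection produced no candidates."""


class HarmonizationError(MRKitError):
    """Harmonization produced an empty instrument set."""


class DegenerateInstrumentError(MRKitError):
    """An instrument has a zero SNP-exposure effect; the Wald ratio is undefined."""


class EstimationError(MRKitError):
    """An estimator's preconditions (minimum instrument count, non-collinearity) fail."""


class PipelineStageError(MRKitError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}': {cause}")
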