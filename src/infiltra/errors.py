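"""Exception hierarchy shared across the pipeline."""


class InfiltraError(Exception):
    """Base class for all package errors."""


class ConfigurationError(InfiltraError):
    """Invalid generator or analysis configuration."""


class InputError(InfiltraError):
    """Malformed or inconsistent input data."""


class PlacementError(InfiltraError):
    """Synthetic cells could not be placed within the retry budget."""


class ROIError(InfiltraError):
    """Degenerate or out-of-bounds region of interest."""


class CalibrationError(InfiltraError):
    """White-balance calibration failed."""


class InsufficientContrastError(CalibrationError):
    """Background and foreground references are indistinguishable."""


class UndefinedRatioError(InfiltraError):
    """Denominator class absent; ratio undefined (flag, do not coerce to 0)."""


class AdjudicationNeededError(InfiltraError):
    """Counter discrepancy exceeds threshold and no referee was supplied."""


class ConsensusNeededError(InfiltraError):
    """Score spread exceeds threshold and no consensus value was supplied."""


class ResolutionError(InfiltraError):
    """Allele resolution does not match the genotype table."""


class NoEventsError(InfiltraError):
    """No events observed; rank-based survival comparison undefined."""

    def __init__(self, message, fit=None):
        super().__init__(message)
        self.fit = fit


class FitError(InfiltraError):
    """Model fit failed to converge."""


class InternalStandardError(InfiltraError):
    """Heavy internal-standard signal absent; abundance cannot be computed."""


class ReferenceBindingError(InfiltraError):
    """Reference peptide shows no measurable binding; ratio undefined."""
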