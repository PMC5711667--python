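"""Exception hierarchy for the PT/INR harmonization pipeline."""


class PtInrError(Exception):
    """Base class for all package errors."""


class FormatError(PtInrError, ValueError):
    """A table or document does not have the expected structure."""


class ValidationError(PtInrError, ValueError):
    """Structurally valid input with values that violate a domain constraint."""


class DegenerateDesignError(PtInrError, ValueError):
    """A regression or test design without enough information to proceed
    (fewer than three distinct calibrant levels, zero predictor variance,
    a contingency table with an empty margin, ...)."""


class ConfigurationError(PtInrError, ValueError):
    """A required piece of configuration is missing (no calibration line for a
    correctable method, no mean-normal PT for the ISI measurement model, ...)."""
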