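"""Exception hierarchy."""


class RctAugmentError(Exception):
    """Base class for package errors."""


class ConfigurationError(RctAugmentError):
    """Invalid generator or study configuration."""


class CalibrationError(RctAugmentError):
    """Prevalence calibration could not reach the requested eligible fraction."""


class FitError(RctAugmentError):
    """A model fit failed to converge or the design was unusable."""


class DegenerateOutcomeError(RctAugmentError):
    """Outcome has fewer than two observed categories."""


class ScenarioError(RctAugmentError):
    """Too many replicate failures within a scenario."""
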