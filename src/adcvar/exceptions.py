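"""Exception hierarchy for the adcvar package."""


class AdcVarError(Exception):
    """Base class for all adcvar-specific errors."""


class ConfigError(AdcVarError):
    """Raised for invalid or inconsistent pipeline configuration."""


class InfeasibleTargetError(AdcVarError):
    """Raised when no tissue diffusivity can reproduce a requested ADC."""


class InvalidSubsetError(AdcVarError):
    """Raised for b-value subsets that cannot support an ADC fit."""


class NoEvaluableROIError(AdcVarError):
    """Raised when an ROI is empty after exclusions and invalid voxels."""


class DegenerateSplitError(AdcVarError):
    """Raised when a median split leaves one group empty."""


class InsufficientDataError(AdcVarError):
    """Raised when fewer observations are available than a statistic needs."""
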