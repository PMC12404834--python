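"""Exception and warning types shared across the package."""


class RobustMRError(Exception):
    """Base class for all package errors."""


class ConfigError(RobustMRError):
    """A configuration problem: missing column mapping, bad study config key."""


class ValidationError(RobustMRError):
    """Input data violate a structural invariant (non-positive SE, duplicate SNP...)."""

    def __init__(self, message, snp_ids=None):
        super().__init__(message)
        self.snp_ids = list(snp_ids) if snp_ids is not None else []


class EmptyDatasetError(RobustMRError):
    """An operation produced or received a dataset with no usable SNPs."""


class DegenerateInstrumentsError(RobustMRError):
    """Estimator denominator is zero/non-positive; no information in the instruments."""


class InstrumentStrengthError(RobustMRError):
    """dIVW denominator <= 0: instruments too weak for the debiasing correction."""


class UnderIdentifiedError(RobustMRError):
    """Fewer SNPs than exposures (or otherwise rank-deficient design)."""


class ConvergenceError(RobustMRError):
    """Optimizer or sampler failed and no honest estimate can be reported."""


class WeakInstrumentWarning(UserWarning):
    """Raised (as a warning) when the dIVW condition measure falls below its floor."""
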