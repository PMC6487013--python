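"""Exception hierarchy used across the package."""


class SowscanError(Exception):
    """Base class for all package errors."""


class ConfigError(SowscanError):
    """Invalid configuration (counts, ranges, thresholds)."""


class PedigreeError(SowscanError):
    """Structural pedigree problem: cycles, duplicates, bad parents."""


class DataError(SowscanError):
    """Content problem in input data (monomorphic SNPs, bad CNV lines...)."""


class ConvergenceError(SowscanError):
    """Iterative estimation failed to converge.

    Carries the iteration trajectory for diagnosis.
    """

    def __init__(self, message, trajectory=None):
        super().__init__(message)
        self.trajectory = trajectory or []
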