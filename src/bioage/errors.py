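"""Exception hierarchy shared across the package."""


class BioageError(Exception):
    """Base class for all package errors."""


class ConfigurationError(BioageError):
    """An invalid configuration value (negative SD, bad schedule, ...)."""


class MissingFeatureError(BioageError):
    """A clock feature is absent and no reference median covers it."""

    def __init__(self, features):
        self.features = sorted(features)
        super().__init__(f"missing features with no reference median: {self.features}")


class InsufficientDataError(BioageError):
    """Too few samples / subjects / replicates for the requested statistic."""


class DegenerateDataError(BioageError):
    """Zero-variance or otherwise degenerate input (undefined ICC, constant clock)."""


class SingularDesignError(BioageError):
    """Rank-deficient regression design."""


class UntrainableModelError(BioageError):
    """No biomarker survived the retention filter; the model cannot be fit."""
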