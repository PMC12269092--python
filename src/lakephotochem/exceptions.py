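"""Exception and warning types shared across the package."""


class LakePhotoError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(LakePhotoError, ValueError):
    """An argument violates a documented precondition."""


class OutOfRangeError(LakePhotoError, ValueError):
    """A wavelength or index falls outside the supported range."""


class UndefinedMetricError(LakePhotoError, ArithmeticError):
    """A metric is mathematically undefined for the given input (e.g. x/0)."""


class FitFailureError(LakePhotoError, RuntimeError):
    """A regression or optimisation could not produce a usable estimate."""


class InsufficientDataError(LakePhotoError, ValueError):
    """Too few observations to evaluate the statistic."""


class InvalidInputError(LakePhotoError, ValueError):
    """Input data are malformed (non-finite, unsorted, wrong shape...)."""


class InvalidConfigurationError(LakePhotoError, ValueError):
    """Configured constants are internally inconsistent."""


class SuspectResultWarning(UserWarning):
    """A computed quantity is outside its physically plausible range."""


class DegenerateClusteringWarning(UserWarning):
    """Clustering input carries no structure; a trivial assignment was made."""
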