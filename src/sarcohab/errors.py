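"""Exception hierarchy shared across the package."""


class SarcohabError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SarcohabError, ValueError):
    """A generator or pipeline configuration is invalid."""


class InputError(SarcohabError, ValueError):
    """Mismatched, malformed, or otherwise unusable input data."""


class EmptyRoiError(InputError):
    """A region of interest contains no foreground voxels."""


class DegenerateInputError(InputError):
    """Input has no structure to exploit (e.g. all intensities identical)."""


class RankDeficiencyError(InputError):
    """A regression design matrix is rank deficient (collinear columns)."""
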