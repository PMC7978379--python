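"""Exception types shared across the package."""


class AlleleBurstError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(AlleleBurstError, ValueError):
    """A kinetic parameter is non-finite, negative, or otherwise out of range."""


class InsufficientDataError(AlleleBurstError, ValueError):
    """Too few usable observations for the requested computation."""


class NoSignalError(InsufficientDataError):
    """All observed counts are zero; kinetics are unidentifiable."""


class SchemaError(AlleleBurstError, ValueError):
    """An input file or table violates the expected schema."""


class CollinearityError(AlleleBurstError, ValueError):
    """The regression design matrix is rank-deficient."""
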