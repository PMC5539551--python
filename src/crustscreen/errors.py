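"""Exception hierarchy shared across the package."""


class CrustScreenError(Exception):
    """Base class for all package-specific errors."""


class TableFormatError(CrustScreenError, ValueError):
    """A tabular input file does not follow the expected layout."""


class ValidationError(CrustScreenError, ValueError):
    """Parsed data violates a domain invariant (duplicates, negatives, ...)."""


class DegenerateSampleError(CrustScreenError, ValueError):
    """A sample has zero library size where a positive one is required."""


class ConfigurationError(CrustScreenError, ValueError):
    """A run configuration is incomplete or inconsistent."""


class BelowDetectionError(CrustScreenError, RuntimeError):
    """A quantification was requested for a below-detection qPCR panel."""
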