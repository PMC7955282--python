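"""Exception hierarchy shared across the package."""


class MRMedError(Exception):
    """Base class for all package errors."""


class ValidationError(MRMedError, ValueError):
    """Input data violates a documented invariant (bad allele, SE <= 0, ...)."""


class ConfigurationError(MRMedError, ValueError):
    """A run configuration or file layout problem (missing column, bad role)."""


class DegenerateDesignError(MRMedError, ValueError):
    """A regression design is rank deficient or otherwise unusable."""
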