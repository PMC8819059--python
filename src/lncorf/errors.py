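"""Exception hierarchy shared across the package."""


class LncorfError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(LncorfError):
    """Raised when an input value violates a documented contract."""


class ConfigurationError(LncorfError):
    """Raised when a run configuration is internally inconsistent."""
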