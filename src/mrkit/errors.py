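"""Exception hierarchy shared across the package."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ConfigurationError(MRKitError):
    """Raised when user-supplied configuration is invalid or incomplete."""


class DataError(MRKitError):
    """Raised when input data violate a contract (empty table, bad values)."""


class DomainError(MRKitError, ValueError):
    """Raised when an operation is called outside its mathematical domain."""
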