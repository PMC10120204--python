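"""Exception hierarchy shared across the package."""


class EndofewError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(EndofewError):
    """A spec/config object is internally inconsistent or out of range."""


class ValidationError(EndofewError):
    """Runtime input violates an operation's contract."""


class ManifestError(EndofewError):
    """A dataset manifest row is malformed or references missing data."""


class MiningError(EndofewError):
    """No valid triplet exists for the requested mining regime."""


class TrainingError(EndofewError):
    """Optimisation failed (e.g. non-finite loss)."""


class SplitError(EndofewError):
    """A train/test or train/validation split cannot satisfy its contract."""
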