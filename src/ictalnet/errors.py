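"""Exception hierarchy for ictalnet."""


class IctalnetError(Exception):
    """Base class for package-specific errors."""


class DataError(IctalnetError, ValueError):
    """A recording or segment violates a data contract (e.g. too few channels)."""


class FormatError(IctalnetError, ValueError):
    """A file on disk does not conform to its declared format."""


class ConfigurationError(IctalnetError, ValueError):
    """A model or run configuration is internally inconsistent."""


class LeakageError(IctalnetError, ValueError):
    """Train and validation sets share patients."""
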