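"""Exception types shared across the pipeline."""


class MetsflowError(Exception):
    """Base class for all package errors."""


class MissingDataError(MetsflowError):
    """A required indicator value is absent from a record."""


class ConfigurationError(MetsflowError):
    """An indicator spec, criteria object or generator config is invalid."""
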