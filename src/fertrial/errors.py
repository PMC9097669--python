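"""Exception hierarchy shared by every fertrial module."""


class FertrialError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(FertrialError):
    """A file violates the expected column/field contract."""


class ParseError(FertrialError):
    """A value could not be parsed; the message names the offending row."""


class IntegrityError(FertrialError):
    """The data violates a design-level requirement (duplicates, imbalance,
    ragged seasons)."""


class DomainError(FertrialError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class ConfigurationError(FertrialError):
    """A required product, price or reference row is missing from the
    configuration."""
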