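"""Exception hierarchy shared across the package."""


class RtpQuantError(Exception):
    """Base class for all package errors."""


class SchemaError(RtpQuantError):
    """A table is missing required columns or has the wrong layout."""


class ValidationError(RtpQuantError):
    """A table parsed but violates a content contract (duplicates, signs, ...)."""


class ConfigError(RtpQuantError):
    """A configuration object or file is invalid; message names the field."""


class AlignmentError(RtpQuantError):
    """Two matrices that must share genes/samples do not."""
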