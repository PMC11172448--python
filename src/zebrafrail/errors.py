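"""Typed exceptions.

Every malformed input raises one of these; the pipeline never silently
fixes up bad data.
"""


class ZebrafrailError(Exception):
    """Base class for all package errors."""


class SchemaError(ZebrafrailError):
    """A table is missing a required column or has an unusable layout."""


class ValidationError(ZebrafrailError):
    """A value violates a domain invariant (non-positive weight, duplicate
    id, non-monotone time, unknown class label, ...)."""


class ConfigError(ZebrafrailError):
    """An analysis configuration is inconsistent or incomplete."""
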