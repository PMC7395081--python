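"""Exception hierarchy used across the package."""


class OctmarkError(Exception):
    """Base class for all package errors."""


class FormatError(OctmarkError):
    """A file is not in a recognised on-disk dialect (e.g. missing sidecar header)."""


class CorruptionError(OctmarkError):
    """A file is recognised but its payload is inconsistent with its header."""


class ValidationError(OctmarkError, ValueError):
    """Input data violate a documented invariant."""
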