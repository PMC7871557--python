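"""Exception hierarchy used across the pipeline."""


class FlabkitError(Exception):
    """Base class for all package errors."""


class FormatError(FlabkitError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(FlabkitError):
    """Input parsed correctly but violates a domain invariant."""


class DegenerateDesignError(FlabkitError):
    """A model fit was requested on data with no usable variation."""
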