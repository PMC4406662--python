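"""Exception types shared across the pipeline."""


class ZrpageError(Exception):
    """Base class for all package errors."""


class ValidationError(ZrpageError):
    """Invalid configuration or malformed input; the message names the field."""


class DegenerateInputError(ZrpageError):
    """Input with zero variance where a scale estimate is required."""


class FormatError(ZrpageError):
    """Malformed file content; the message carries the location."""
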