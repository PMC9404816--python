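"""Exception hierarchy shared across the package."""


class TangleSegError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(TangleSegError, ValueError):
    """A configuration value violates its contract; the message names the field."""


class InputError(TangleSegError, ValueError):
    """A runtime input (array shape, mask content, fold contents) is invalid."""


class FormatError(TangleSegError, ValueError):
    """A file decodes but has the wrong structure (e.g. grayscale where RGB is required)."""
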