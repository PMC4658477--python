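"""Exception types shared across the package."""


class ExactSetsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(ExactSetsError):
    """An input file violates its format contract."""


class ConfigurationError(ExactSetsError):
    """An analysis or simulation was configured inconsistently."""
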