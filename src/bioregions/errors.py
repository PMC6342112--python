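"""Exception types shared across the package."""


class BioregionsError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(BioregionsError, ValueError):
    """Invalid input file layout or configuration (e.g. a missing column)."""


class ParameterError(BioregionsError, ValueError):
    """A parameter value outside its valid domain (e.g. a non-positive grid size)."""
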