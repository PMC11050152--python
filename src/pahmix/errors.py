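"""Exception types shared across the package."""


class PahmixError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PahmixError):
    """A mixture, simulation, or run configuration is invalid or incomplete."""


class UnknownComponentError(PahmixError, KeyError):
    """A component name was looked up that the mixture does not contain."""


class MissingControlError(PahmixError):
    """Vehicle-control observations required for normalization are absent."""


class FitError(PahmixError):
    """No usable dose-response fit could be produced."""
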