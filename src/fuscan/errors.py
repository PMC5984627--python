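"""Exception hierarchy for fuscan."""


class FuscanError(Exception):
    """Base class for all fuscan errors."""


class FormatError(FuscanError):
    """An input file violates its format contract."""


class ConfigurationError(FuscanError):
    """Invalid parameter values or an impossible simulation request."""


class FusionError(FuscanError):
    """A rearrangement cannot be turned into a transcribable fusion."""


class AnalysisError(FuscanError):
    """An analysis step received input it cannot operate on."""
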