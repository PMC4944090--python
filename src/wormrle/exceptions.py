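"""Exception and warning hierarchy for wormrle."""


class WormRLEError(Exception):
    """Base class for all wormrle errors."""


class ParameterError(WormRLEError, ValueError):
    """An invalid parameter value; the message names the offending field."""


class InputError(WormRLEError, ValueError):
    """Input data that violates a precondition (shape, range, coverage)."""


class DegenerateClusteringError(WormRLEError, ValueError):
    """Fewer distinct points than requested clusters."""


class UnsupportedConfigurationError(WormRLEError, ValueError):
    """An operation asked to run under a configuration it does not define."""


class InsufficientDataError(WormRLEError, ValueError):
    """Too few observations for the requested statistic."""


class UndefinedDescriptorError(WormRLEError, ValueError):
    """Descriptors are undefined (no runs in the encoded string)."""


class WormRLEWarning(UserWarning):
    """Base class for wormrle warnings."""


class DegenerateFeatureWarning(WormRLEWarning):
    """A feature had zero range (or zero variance) and was neutralized."""


class EmptyResultWarning(WormRLEWarning):
    """An operation produced an empty result (no movement, no steps, no runs)."""
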