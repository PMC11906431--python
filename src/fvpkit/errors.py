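"""Named exceptions raised across the toolkit."""


class FvpError(Exception):
    """Base class for all fvpkit errors."""


class UnknownProtocolError(FvpError):
    """Stimulation protocol name is not one of the supported protocols."""


class InvalidParameterError(FvpError):
    """A numeric or structural parameter is outside its valid domain."""


class FormatError(FvpError):
    """A file could not be read or written in the requested format."""


class MixedSampleRateError(FormatError):
    """Channels in a recording file carry different sampling rates."""


class ScheduleCoverageError(FvpError):
    """State schedule or recording does not cover the requested span."""


class EmptySelectionError(FvpError):
    """An epoch/event selection matched nothing."""


class WindowError(FvpError):
    """An analysis time window is inverted, degenerate or out of range."""


class MissingChannelError(FvpError):
    """A required channel (by label or kind) is absent from the recording."""


class MissingEpochError(FvpError):
    """An event lacks an epoch on a requested electrode."""


class TooFewEventsError(FvpError):
    """Not enough events to compute the requested index."""


class SingleClassError(FvpError):
    """Decoding requires at least two label classes."""


class ConfigMismatchError(FvpError):
    """Manifests being compared were produced with different analysis settings."""
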