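"""Exception hierarchy shared across the package."""


class HE2STError(Exception):
    """Base class for all package-specific errors."""


class AlignmentError(HE2STError, ValueError):
    """Spot identifiers disagree between the spot table and the counts matrix."""


class EmptySampleError(HE2STError, ValueError):
    """An operation produced or received a sample with zero usable spots."""


class DegenerateChannelError(HE2STError, ValueError):
    """A patch channel has zero standard deviation and cannot be standardized."""


class ConfigError(HE2STError, ValueError):
    """Invalid, missing, or mutually inconsistent configuration values."""
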