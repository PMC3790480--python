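"""Exception hierarchy shared across the pipeline stages."""


class FluvnetError(Exception):
    """Base class for all package errors."""


class TopologyError(FluvnetError):
    """The stream network is not a valid rooted tree."""


class SiteLookupError(FluvnetError, KeyError):
    """A referenced site id is not present in the network."""


class ConfigurationError(FluvnetError):
    """Invalid or inconsistent configuration."""


class DepthError(FluvnetError):
    """Requested rarefaction depth exceeds the available reads."""


class FormatError(FluvnetError):
    """Malformed input file."""


class AlignmentError(FluvnetError):
    """Sample/site ids of two inputs do not line up."""
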