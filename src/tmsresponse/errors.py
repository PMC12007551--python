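"""Exception types shared across the package."""


class TMSResponseError(Exception):
    """Base class for all package errors."""


class SWCParseError(TMSResponseError):
    """An SWC record could not be parsed; the message names the line."""


class TopologyError(TMSResponseError):
    """A section/compartment graph is not a rooted tree."""


class GeometryError(TMSResponseError):
    """Invalid geometric input (non-positive lengths, degenerate axons...)."""


class ConfigurationError(TMSResponseError):
    """Invalid parameter value or unknown option."""


class DivergenceError(TMSResponseError):
    """The cable integration produced non-finite voltages."""


class RangeError(TMSResponseError):
    """Query outside the supported domain (no extrapolation)."""


class EmptyBinError(TMSResponseError):
    """A (theta, delta) bin holds no finite threshold samples."""


class SurrogateConditioningError(TMSResponseError):
    """The gPC regression matrix is too ill-conditioned; draw more samples."""
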