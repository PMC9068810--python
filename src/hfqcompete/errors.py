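"""Exception hierarchy shared across the pipeline stages."""


class HfqCompeteError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(HfqCompeteError):
    """Invalid parameters or malformed configuration input."""


class DataError(HfqCompeteError):
    """Input data violates a structural precondition (overlaps, bounds...)."""


class FlowStepError(DataError):
    """No detectable competitor-addition background step in a Cy5 trace."""


class FitError(HfqCompeteError):
    """Dwell-time fit failed to converge or its inputs are degenerate."""
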