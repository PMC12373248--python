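"""Exception hierarchy shared across the package."""


class ChinpointError(Exception):
    """Base class for all package errors."""


class ValidationError(ChinpointError):
    """Malformed or inconsistent input data (files, records, cohorts)."""


class GeometryError(ChinpointError):
    """Degenerate or ill-conditioned geometric configuration."""


class ParameterError(ChinpointError):
    """A parameter value outside its admissible range."""
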