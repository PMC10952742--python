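"""Exception types shared across the package."""


class PemscopeError(Exception):
    """Base class for package errors."""


class InfeasibleGeometryError(PemscopeError):
    """ROI too small to contain the requested vascular tree."""


class InfeasibleDensityError(PemscopeError):
    """Requested cell density cannot be realized under spacing constraints."""


class NoEligibleVesselError(PemscopeError):
    """No vessel segment satisfies the diameter eligibility criterion."""


class DimensionalityError(PemscopeError):
    """2-D and 3-D coordinates mixed within one table or query."""


class SchemaError(PemscopeError):
    """An input table is missing mandatory columns."""
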