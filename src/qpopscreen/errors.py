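"""Exception hierarchy shared across the pipeline stages."""


class QPOPError(Exception):
    """Base class for all qpopscreen errors."""


class InputError(QPOPError):
    """Malformed or out-of-contract input (bad columns, bad levels, bad x)."""


class DegenerateFitError(QPOPError):
    """Dose-response data carry no dose effect; a 4PL fit is meaningless."""


class UnresolvableDoseError(QPOPError):
    """Neither the ICx rule nor the Cmax-fraction rule can assign screen doses."""


class UnsupportedSizeError(QPOPError):
    """Requested design size falls outside the construction catalogue."""


class SingularDesignError(QPOPError):
    """The second-order model matrix is rank deficient for this design."""


class InsufficientDataError(QPOPError):
    """Fewer runs than model coefficients; the regression is underdetermined."""


class SearchSpaceError(QPOPError):
    """Full 3^k enumeration was requested for a k that is too large."""
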