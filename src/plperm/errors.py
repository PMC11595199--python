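"""Exception hierarchy shared across the package."""


class PlpermError(Exception):
    """Base class for all package-specific errors."""


class ParseError(PlpermError):
    """A delimited input file could not be parsed (names the offending cell)."""


class ValidationError(PlpermError):
    """A domain invariant was violated (duplicate ids, missing response, ...)."""


class RankError(PlpermError):
    """Design matrix is rank deficient; message names collinear columns."""


class ApplicabilityError(PlpermError):
    """A similarity-based prediction could not be made (all similarities ~ 0)."""
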