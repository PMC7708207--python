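"""Exception hierarchy.

Parse errors (malformed input files) and computation errors (invalid
numerical input, sampler failure) are kept distinct so the CLI can map
them to different exit codes.
"""


class SDIError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SDIError, ValueError):
    """A value violates an operation's preconditions."""


class ParseError(SDIError, ValueError):
    """A count-table file could not be parsed/validated."""


class BoundaryError(InvalidInputError):
    """A probability sits on the boundary {0, 1} where a formula is undefined."""


class DegenerateInputError(InvalidInputError):
    """Input is valid but degenerate for the requested operation."""


class SamplerFailureError(SDIError, RuntimeError):
    """The MCMC sampler could not obtain a valid state."""
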