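"""Exception hierarchy for phsorb.

All errors derive from :class:`PhsorbError` so callers can catch the
package's failures with one clause; the CLI maps them to stage-tagged
messages and a nonzero exit code.
"""


class PhsorbError(Exception):
    """Base class for all phsorb errors."""


class InvalidInputError(PhsorbError, ValueError):
    """A value violates a precondition (sign, range, missing field)."""


class InvalidDesignError(PhsorbError, ValueError):
    """An experimental design cannot support the requested estimate
    (e.g. fewer than two distinct pH levels for a two-parameter fit)."""


class IdentifiabilityError(PhsorbError, ValueError):
    """The design leaves a parameter combination unresolvable: the neutral
    fraction is constant across all observations while both species are
    present, so only the mixture K_P,n*f_n + K_P,i*f_i is estimable."""


class InfeasibleError(PhsorbError, ValueError):
    """A requested error bound lies below the analytical error floor
    eps/(1+eps) and cannot be met at any partition coefficient."""


class ParseError(PhsorbError, ValueError):
    """A CSV cell or header failed validation; the message names the
    offending row and column."""


class PipelineError(PhsorbError, RuntimeError):
    """A pipeline stage failed; the message names the stage and compound."""
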