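"""Exception hierarchy.

All package-specific failures derive from :class:`AgevarError` so callers
(and the CLI) can distinguish scientific/contract errors from programming
bugs.
"""


class AgevarError(Exception):
    """Base class for all errors raised by agevar."""


class SpecError(AgevarError, ValueError):
    """Invalid scenario parameterisation or configuration input."""


class TrajectoryError(AgevarError, ValueError):
    """Age outside the modelled range, or a trajectory leaving the domain
    where the linear decline models are valid (value < 0, mean <= 0)."""


class CohortError(AgevarError, ValueError):
    """Malformed cohort data or cohort file (missing columns, bad rows,
    design violations)."""


class BinningError(AgevarError, ValueError):
    """Invalid age-bin layout or underpopulated bins."""


class TrendError(AgevarError, ValueError):
    """Trend inference could not be carried out under its contract."""
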