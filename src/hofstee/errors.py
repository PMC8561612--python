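"""Exception hierarchy shared across the package.

Each class maps to a distinct CLI exit code so that scripted callers can
tell an unreadable file apart from bad judge parameters or a curve that
never meets line AB.
"""

from __future__ import annotations


class HofsteeError(Exception):
    """Base class for all errors raised by this package."""

    exit_code = 1


class InputError(HofsteeError):
    """A file could not be read or contained no usable data."""

    exit_code = 3


class ValidationError(HofsteeError):
    """A value violates the method's domain constraints (range/ordering)."""

    exit_code = 4


class NoIntersectionError(HofsteeError):
    """Line AB and the cumulative curve do not cross.

    ``direction`` records which side the curve lies on over the parameter
    window: ``"above"`` (more students failing than f_max allows at every
    candidate score — consider raising f_max or lowering c_min) or
    ``"below"`` (fewer than f_min would fail — consider lowering f_min or
    raising c_max).  A cohort whose scores fall entirely outside
    [c_min, c_max] is classified the same way: all above the window means
    0% failing ("below"), all below means 100% ("above").
    """

    exit_code = 5

    def __init__(self, message: str, direction: str):
        super().__init__(message)
        self.direction = direction
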