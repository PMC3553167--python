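"""Exception hierarchy.

All package errors derive from :class:`SexAllocError` so callers can catch
broadly; the subclasses distinguish bad inputs (``DomainError``), model
configurations that violate a biological invariant (``ValidationError``),
and operations applied to an unsupported curve family.
"""


class SexAllocError(ValueError):
    """Base class for all package errors."""


class DomainError(SexAllocError):
    """An argument lies outside the mathematical domain of an operation."""


class ValidationError(SexAllocError):
    """A model configuration violates a biological invariant (e.g. C(E) > 1)."""


class UnsupportedFamilyError(SexAllocError):
    """A closed-form operation was requested for a curve family without one."""


class InsufficientDataError(SexAllocError):
    """Too few usable groups to estimate the elasticity."""


class BracketingError(SexAllocError):
    """A root finder was given an interval with no sign change."""
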