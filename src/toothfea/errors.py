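"""Exception types used across the pipeline.

The CLI maps :class:`UserError` subclasses to exit code 1 and anything else
to exit code 2.
"""


class ToothFEAError(Exception):
    """Base class for all package errors."""


class UserError(ToothFEAError):
    """Invalid input supplied by the caller (bad parameters, bad files)."""


class ValidationError(UserError):
    """A parameter or data-structure invariant was violated."""


class MeshError(ToothFEAError):
    """A mesh failed a structural or geometric check (e.g. inverted element)."""


class ContactError(UserError):
    """Contact detection could not proceed (no contact reachable, bad inputs)."""


class LoadError(UserError):
    """A load case could not be constructed (no contacts, degenerate normals)."""


class ConstraintError(UserError):
    """Boundary constraints are insufficient or inconsistent."""


class SolverError(ToothFEAError):
    """The linear solve failed (singular or non-finite system)."""
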