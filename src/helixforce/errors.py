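"""Exception hierarchy for helixforce.

Every error raised by the library derives from :class:`HelixForceError`, so
callers (and the CLI) can catch one type and report a single-line reason.
"""


class HelixForceError(Exception):
    """Base class for all helixforce errors."""


class ValidationError(HelixForceError):
    """Input data violates a documented invariant (bad annotation, short helix, ...)."""


class EmptySelectionError(HelixForceError):
    """A structure file contained no ATOM records for the requested model/chain."""


class DegenerateGeometryError(HelixForceError):
    """Geometry too degenerate to fit (coincident points, sidechain on the axis, ...)."""


class FrameMismatchError(HelixForceError):
    """Transforms composed across incompatible coordinate frames."""


class ChargeAssignmentError(HelixForceError):
    """A residue name has no entry in the charge table."""
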