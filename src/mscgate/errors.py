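"""Exception hierarchy.

Every error raised on a documented failure path derives from
:class:`MscgateError` so callers (and the CLI) can separate stage failures
from programming errors.
"""


class MscgateError(Exception):
    """Base class for all mscgate stage errors."""


class FormatError(MscgateError):
    """Input file could not be parsed in the requested format."""


class EmptyStructureError(MscgateError):
    """A parsed structure contains no protein atoms."""


class SymmetryError(MscgateError):
    """No rotational symmetry with acceptable self-agreement was found.

    Carries the best candidate so callers can inspect it.
    """

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class OrientationError(MscgateError):
    """Periplasmic marker selection was empty; polarity cannot be set."""


class SlabError(MscgateError):
    """Membrane slab is invalid (too thin, outside the structure, or no
    hydrophobic belt found)."""


class SelectionError(MscgateError):
    """A residue/chain selection matched no atoms."""


class InsufficientDataError(MscgateError):
    """Too few points/atoms to perform the requested measurement."""


class ConventionError(MscgateError):
    """Two per-state profiles were measured under different slab conventions."""


class RangeError(MscgateError):
    """Requested axial range lies outside the structure."""


class MidpointError(MscgateError):
    """No positive midpoint tension exists (theta_c^2*R_c <= theta_o^2*R_o)."""


class IncompleteDeltaError(MscgateError):
    """StateDelta is missing fields required to build gating parameters."""


class NoEventsError(MscgateError):
    """Current-amplitude histogram is unimodal; no resolvable openings."""


class NoActivationError(MscgateError):
    """No event of the requested amplitude class occurred on the ramp."""


class SpecError(MscgateError):
    """A synthetic-data specification is internally inconsistent."""
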