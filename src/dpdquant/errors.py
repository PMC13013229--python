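"""Exception hierarchy.

Every failure mode raised by dpdquant derives from :class:`DPDQuantError`, so
callers (and the CLI) can distinguish data errors from programming errors.
"""


class DPDQuantError(Exception):
    """Base class for all dpdquant errors."""


class UnitError(DPDQuantError):
    """A volume carried the wrong unit tag for the requested operation."""


class InvalidDoseError(DPDQuantError):
    """Dose record with non-positive activity/weight or acquisition before injection."""


class ParameterError(DPDQuantError):
    """An out-of-range configuration or function parameter."""


class GeometryError(DPDQuantError):
    """Inconsistent or degenerate grid geometry (shape mismatch, non-orthonormal axes)."""


class EmptyStructureError(DPDQuantError):
    """A marker was requested over an empty mask."""


class MissingStructureError(DPDQuantError):
    """A required canonical structure is absent from the structure set."""


class DegenerateGeometryError(DPDQuantError):
    """Voxel grid too coarse for the requested VOI (e.g. SUVpeak sphere < 1 voxel)."""


class InvalidReferenceError(DPDQuantError):
    """Background/reference statistic unusable (empty IVC, non-positive mean, zero T9 peak)."""


class PhantomSpecError(DPDQuantError):
    """Invalid phantom specification (overlapping exclusive structures, out-of-grid shape)."""


class InsufficientDataError(DPDQuantError):
    """Too few observations for the requested statistical test."""


class DegenerateVarianceError(DPDQuantError):
    """Zero between-subject variance: ICC undefined."""


class NoEventsError(DPDQuantError):
    """Survival analysis requested on a cohort with no observed events."""


class ConvergenceError(DPDQuantError):
    """A model fit failed to converge; the message names the marker."""
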