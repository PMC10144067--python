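"""Exception hierarchy for the fieldlisa pipeline.

Every stage raises a subclass of :class:`FieldLisaError` so that the
orchestrator can abort with the stage name and the offending input.
"""


class FieldLisaError(Exception):
    """Base class for all fieldlisa errors."""


class InvalidParameterError(FieldLisaError, ValueError):
    """A configuration parameter is out of its documented domain."""


class InvalidInputError(FieldLisaError, ValueError):
    """An input table or array violates a precondition (length, emptiness)."""


class RasterAlignmentError(FieldLisaError, ValueError):
    """Two rasters that must share shape, origin and cell size do not."""


class OutOfExtentError(FieldLisaError, ValueError):
    """A plant point falls outside the raster extent."""


class DegenerateVarianceError(FieldLisaError, ValueError):
    """All values identical: standardization or rank tests are undefined."""


class NoNeighborsError(FieldLisaError, ValueError):
    """Every point is isolated at the given distance threshold."""


class ConsistencyError(FieldLisaError, ValueError):
    """Mutually exclusive region memberships overlap."""
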