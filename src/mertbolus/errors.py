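"""Exception hierarchy shared across the package."""


class BolusError(Exception):
    """Base class for all package errors."""


class FormatError(BolusError):
    """A file could not be parsed as the expected format."""


class GeometryError(BolusError):
    """Inconsistent or missing spatial geometry (spacing, orientation, tags)."""


class AlignmentError(BolusError):
    """Two spatial objects do not overlap or reference different frames."""


class SpecError(BolusError):
    """An invalid phantom/design specification."""


class SerializationError(BolusError):
    """Output could not be serialized (e.g. non-finite mesh vertices)."""


class ConvergenceError(BolusError):
    """An iterative procedure failed to converge."""


class MetricError(BolusError):
    """Plan metrics undefined for the given inputs (e.g. empty PTV)."""
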