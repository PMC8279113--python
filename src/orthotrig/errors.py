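"""Exception types shared across the package."""


class OrthotrigError(Exception):
    """Base class for all package-specific errors."""


class MalformedFileError(OrthotrigError):
    """An input file violates its format's structural rules."""


class ValidationError(OrthotrigError):
    """A table or data model violates a schema or domain invariant."""


class DegenerateGeometryError(OrthotrigError):
    """Geometry is rank-deficient (collinear points, too few landmarks...)."""


class DegenerateToothError(DegenerateGeometryError):
    """A single tooth's landmarks cannot support an angular measurement."""

    def __init__(self, tooth_id, message):
        self.tooth_id = tooth_id
        super().__init__(f"tooth {tooth_id}: {message}")
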