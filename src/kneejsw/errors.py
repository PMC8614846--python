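"""Exception types raised across the kneejsw pipeline."""


class KneeJSWError(Exception):
    """Base class for all kneejsw errors."""


class FormatError(KneeJSWError):
    """A file could not be read as a radiograph or label mask."""


class InvalidSpecError(KneeJSWError):
    """A phantom specification violates its geometric invariants."""


class NoJointOverlapError(KneeJSWError):
    """Femur and tibia share no image columns; no joint space exists."""


class OrientationError(KneeJSWError):
    """The femur does not lie above the tibia in the shared column range."""


class DegeneratePlateauError(KneeJSWError):
    """The tibial plateau margin spans too few columns to define a frame."""


class MissingSiteError(KneeJSWError):
    """A requested normalized location maps outside the margin overlap."""

    def __init__(self, x: float, message: str | None = None):
        self.x = x
        super().__init__(message or f"site x={x:g} lies outside the margin overlap")


class ProfileInvalidError(KneeJSWError):
    """Too many sampling sites are missing for the JSW profile to be trusted."""
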