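"""Exception hierarchy for the mpmri pipeline.

Every error raised deliberately by this package derives from
:class:`MpmriError`, so callers can catch pipeline failures without
swallowing programming errors.
"""


class MpmriError(Exception):
    """Base class for all mpmri errors."""


class FormatError(MpmriError):
    """A file could not be parsed as the declared format."""


class LayoutError(MpmriError):
    """Declared axis layout is inconsistent with the array shape."""


class ParameterError(MpmriError):
    """An operation received an invalid parameter value."""


class EmptyRoiError(MpmriError):
    """A region of interest contains no voxels."""


class IntegrityError(MpmriError):
    """A table violates its uniqueness or consistency invariants."""


class NoBolusError(MpmriError):
    """No contrast-agent bolus could be detected in a dynamic series."""


class FitError(MpmriError):
    """A model fit could not be performed on the given data."""


class InputError(MpmriError):
    """A statistical routine received an empty or unusable sample."""


class GeneratorSpecError(MpmriError):
    """A synthetic-data specification is infeasible or invalid."""


class ConfigError(MpmriError):
    """A run configuration is missing required fields or inconsistent."""


class StageError(MpmriError):
    """A pipeline stage failed; carries the stage name for reporting."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
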