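"""Exception hierarchy shared across the pipeline stages."""


class BraincodeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(BraincodeError):
    """A file or array does not have the expected layout (e.g. multi-channel)."""


class ParameterError(BraincodeError):
    """A parameter is outside its valid range or a precondition is violated."""


class RegistrationError(BraincodeError):
    """A volume does not share the template grid of the collection."""


class EmptyRegionError(BraincodeError):
    """An operation left no analysis voxels."""


class ConsistencyError(BraincodeError):
    """Two inputs that must describe the same voxel set do not."""


class PackingError(BraincodeError):
    """Synthetic units could not be placed on the requested grid."""


class PipelineError(BraincodeError):
    """A pipeline stage failed; carries the stage name and the cause."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
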