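"""Exception hierarchy for the screening pipeline."""


class BarcodeError(Exception):
    """Base class for all pipeline errors."""


class VideoReadError(BarcodeError):
    """The container could not be read at all."""


class MalformedVideoError(BarcodeError):
    """The container was readable but frames are inconsistent."""


class AxisAmbiguityError(BarcodeError):
    """Array axes cannot be assigned to (T, m, n, c) without a hint."""


class ParameterError(BarcodeError):
    """A user-supplied parameter is out of its valid range."""


class PipelineError(BarcodeError):
    """A branch received inputs violating its contract (e.g. empty record list)."""
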