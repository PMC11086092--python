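"""Exception types shared across the pipeline."""


class ParameterError(ValueError):
    """An argument is outside its documented domain."""


class DegenerateSeriesError(ValueError):
    """The input series carries no usable structure (constant, too short...)."""


class RecordingIOError(IOError):
    """A recording could not be read or failed validation on load."""
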