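"""Package-specific exception types."""


class InvalidStateError(RuntimeError):
    """An operation was applied to data in the wrong pipeline state.

    Raised e.g. when the modified-YUV transform is applied to a map that has
    already left the RGB color space.
    """


class ConfigurationError(ValueError):
    """A configuration is internally inconsistent or incompatible with the data.

    Raised e.g. when a blood-pressure group contains no subjects so a balanced
    1:1:1:1 batch cannot be formed, or when slice length differs between
    extraction and model.
    """
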