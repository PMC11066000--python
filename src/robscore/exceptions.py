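"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class SchemaError(ValueError):
    """A tabular input does not match the expected CSV schema."""


class MarkerLostError(RuntimeError):
    """The tracked marker could not be located in a video frame."""

    def __init__(self, frame_index: int, message: str | None = None):
        self.frame_index = frame_index
        super().__init__(
            message or f"marker lost at frame {frame_index}: no blob within search radius"
        )
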