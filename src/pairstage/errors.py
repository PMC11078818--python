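"""Exception types shared across the package."""


class DataFormatError(ValueError):
    """A file on disk does not conform to the expected tabular layout."""


class ValidationError(ValueError):
    """An in-memory object violates a structural invariant."""


class StageError(RuntimeError):
    """A pipeline stage produced zero features; names the offending stage."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
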