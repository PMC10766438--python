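"""Exception types shared across the pipeline."""


class FormatError(ValueError):
    """A file violated the expected on-disk format (bad column, bad value)."""


class ContractError(ValueError):
    """An operation was called with arguments violating its contract."""


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name for the manifest."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
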