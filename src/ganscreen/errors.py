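"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input value violates a documented precondition; names the field."""


class ConfigurationError(ValueError):
    """A configuration combination is unsupported (e.g. bad resolution)."""


class TrainingDivergenceError(RuntimeError):
    """A loss became non-finite during optimization; carries the step index."""

    def __init__(self, step: int, what: str = "loss"):
        self.step = step
        super().__init__(f"non-finite {what} at step {step}")
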