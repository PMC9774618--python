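"""Exception hierarchy for moralcan."""


class MoralcanError(Exception):
    """Base class for all package errors."""


class ValidationError(MoralcanError):
    """Input data violates a schema or value constraint."""


class MissingCellError(ValidationError):
    """A dilemma cell has no responses, so its probability is undefined."""

    def __init__(self, cells):
        self.cells = tuple(cells)
        names = ", ".join(c.name if hasattr(c, "name") else str(c) for c in self.cells)
        super().__init__(f"no responses for cell(s): {names}")


class InfeasibleParameterError(MoralcanError):
    """A (AT, ET, OP, D) combination maps to a probability outside [0, 1]."""

    def __init__(self, slot: int, value: float):
        self.slot = slot
        self.value = value
        super().__init__(
            f"parameters imply p{slot} = {value:.4f}, outside [0, 1]"
        )


class ConfigError(MoralcanError):
    """A configuration object is internally inconsistent."""


class ZeroVarianceError(MoralcanError):
    """A statistic is undefined because the relevant variance is zero."""
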