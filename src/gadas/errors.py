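"""Exception taxonomy for the gadas package.

Every error raised by the library derives from :class:`GadasError` so callers
(and the CLI) can distinguish validation failures (exit code 2) from I/O
failures (exit code 3).
"""

from __future__ import annotations


class GadasError(Exception):
    """Base class for all gadas errors."""


class ValidationError(GadasError):
    """A patient record or configuration value failed validation."""


class MissingInputError(ValidationError):
    """A required input field is absent ("missing-input")."""

    def __init__(self, field: str):
        self.field = field
        super().__init__(f"missing-input: required field {field!r} is absent")


class RangeError(ValidationError):
    """A value lies outside its permitted range ("range")."""

    def __init__(self, field: str, value, bound: str):
        self.field = field
        self.value = value
        self.bound = bound
        super().__init__(f"range: {field}={value!r} violates {bound}")


class UnreachableOpeningError(GadasError):
    """No mandible rotation in (0°, 70°] achieves the measured mouth opening."""

    def __init__(self, mouth_opening_mm: float, reachable: tuple[float, float]):
        self.mouth_opening_mm = mouth_opening_mm
        self.reachable = reachable
        super().__init__(
            "unreachable-opening: mouth opening "
            f"{mouth_opening_mm:.1f} mm outside the template's reachable gap "
            f"range [{reachable[0]:.1f}, {reachable[1]:.1f}] mm"
        )


class ConfigError(GadasError):
    """Inconsistent or degenerate model configuration."""


class DegenerateLabelsError(GadasError):
    """Both outcome classes are required but only one is present."""


class ParseError(GadasError):
    """A cohort/result file could not be parsed."""

    def __init__(self, message: str, column: str | None = None, line: int | None = None):
        self.column = column
        self.line = line
        super().__init__(message)


class SimulationError(GadasError):
    """An upstream stage failed during patient simulation; names the stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"simulation failed at stage {stage!r}: {cause}")
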