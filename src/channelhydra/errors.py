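"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`ChannelHydraError` so callers can catch analysis failures without
masking programming errors.
"""


class ChannelHydraError(Exception):
    """Base class for all errors raised by channelhydra."""


class TopologyFormatError(ChannelHydraError):
    """A PDB record could not be parsed; carries the 1-based line number."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class EmptyInputError(ChannelHydraError):
    """An input contained no usable records (e.g. a PDB with no atoms)."""


class SelectionSyntaxError(ChannelHydraError):
    """A selection expression failed to parse; carries the character position."""

    def __init__(self, expression: str, message: str, position: int = 0):
        self.expression = expression
        self.position = position
        super().__init__(f"at position {position} in {expression!r}: {message}")


class ConsistencyError(ChannelHydraError):
    """Two inputs disagree (e.g. trajectory atom count vs topology)."""


class TruncatedTrajectoryError(ChannelHydraError):
    """Trajectory file holds fewer frames than its header promises."""

    def __init__(self, frames_readable: int, frames_declared: int, path: str):
        self.frames_readable = frames_readable
        self.frames_declared = frames_declared
        super().__init__(
            f"{path}: header declares {frames_declared} frames but only "
            f"{frames_readable} are readable (truncated at frame {frames_readable})"
        )


class DomainError(ChannelHydraError):
    """An argument is outside the mathematical domain of an operation."""


class ComparabilityError(ChannelHydraError):
    """Two report bundles were produced with incompatible configurations."""

    def __init__(self, differing_fields: list[str]):
        self.differing_fields = differing_fields
        super().__init__(
            "bundles are not comparable; differing fields: "
            + ", ".join(differing_fields)
        )


class StageError(ChannelHydraError):
    """A pipeline stage failed; names the stage and chains the cause."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {cause}")
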