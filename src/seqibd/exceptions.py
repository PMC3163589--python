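"""Exception hierarchy.

``ValidationError`` covers bad user input (out-of-range coordinates,
mismatched ids, impossible class counts).  ``UntestableError`` is the
distinct "no variation" signal a Mantel statistic emits when one of the
masked distance vectors is constant — callers that can represent an
untestable outcome (the correlogram) catch it; everyone else propagates.
"""


class SeqIBDError(Exception):
    """Base class for all package errors."""


class ValidationError(SeqIBDError, ValueError):
    """Invalid input: names the offending field or ids in its message."""


class AlignmentShapeError(SeqIBDError, ValueError):
    """Rows of an alignment differ in length; names the offending record."""


class FormatError(SeqIBDError, ValueError):
    """Unparseable or empty input file."""


class UntestableError(SeqIBDError):
    """A masked distance vector has zero variance: no testable variation.

    Distinct from a numeric error; the correlogram converts this into a
    ``testable = False`` class row instead of failing.
    """


class NoColumnsError(SeqIBDError, ValueError):
    """An alignment filter removed every column."""


class PipelineStageError(SeqIBDError, RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
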