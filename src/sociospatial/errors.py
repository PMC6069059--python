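"""Exception hierarchy.

All package errors derive from :class:`SociospatialError` so callers can
catch one type at a pipeline boundary while still distinguishing schema
problems from domain-rule violations.
"""


class SociospatialError(Exception):
    """Base class for all errors raised by this package."""


class SchemaError(SociospatialError):
    """A file is structurally unusable: missing column, bad geometry,
    duplicate identifier. The message names the offending column/id."""


class ValidationError(SociospatialError):
    """A value violates a domain invariant (score out of [0,100],
    negative radius, unknown frequency category, ...)."""


class MissingScoreError(SociospatialError):
    """A health-score transform was requested for a participant whose
    score is flagged missing."""


class NoSupporterError(SociospatialError):
    """A best-supporter query found no dyad for the receiver."""


class StageError(SociospatialError):
    """Wraps any error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
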