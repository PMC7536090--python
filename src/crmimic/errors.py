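"""Exception hierarchy for the crmimic pipeline.

Every reader and validator raises a named error instead of silently
repairing inconsistent input.
"""


class CrmimicError(Exception):
    """Base class for all crmimic errors."""


class ParseError(CrmimicError):
    """A file could not be parsed; the message names the offending location."""


class ValidationError(CrmimicError):
    """An input object or parameter violates a documented invariant."""


class SignatureNotRepresentedError(CrmimicError):
    """No probe in the ranked list maps to any gene of the signature."""


class DegenerateSampleError(CrmimicError):
    """A sample has too few usable probe values to be ranked."""


class StageError(CrmimicError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause
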