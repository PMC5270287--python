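"""Exception hierarchy for famseq.

All package-specific errors derive from :class:`FamseqError` so callers can
catch one base class at pipeline boundaries.
"""


class FamseqError(Exception):
    """Base class for all famseq errors."""


class ParseError(FamseqError):
    """A file could not be parsed; the message names the file and, where
    possible, the offending line."""


class VocabularyError(ParseError):
    """A categorical token (effect, impact, phenotype code, chromosome) is not
    in the declared closed vocabulary."""


class ConfigError(FamseqError):
    """A configuration problem detected before any computation starts
    (missing input path, unknown annotation key, bad threshold)."""


class UndefinedOddsRatioError(FamseqError):
    """A 2x2 table contains a zero cell and the continuity correction is
    disabled, so the odds ratio is not a finite number."""


class PipelineStageError(FamseqError):
    """A pipeline stage failed; carries the stage name and the original cause."""

    def __init__(self, stage: str, cause: BaseException):
        self.stage = stage
        self.cause = cause
        super().__init__(f"pipeline stage '{stage}' failed: {cause}")
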