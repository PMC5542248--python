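"""Exception hierarchy for the ocri2 pipeline.

Every error raised by the package derives from :class:`Ocri2Error`, so
callers (and the CLI) can catch pipeline failures without masking
programming errors.
"""


class Ocri2Error(Exception):
    """Base class for all ocri2 errors."""


class FormatError(Ocri2Error):
    """A file does not conform to the expected dialect (columns, types)."""


class IntegrityError(Ocri2Error):
    """Parsed data violates a structural invariant (duplicates, negatives)."""


class InsufficientDataError(Ocri2Error):
    """Too few observations for the requested operation."""


class DegenerateSampleError(Ocri2Error):
    """Sample has zero spread; automatic bandwidth selection is impossible."""


class ConfigurationError(Ocri2Error):
    """Invalid profile, model spec, or run configuration."""


class TrainingError(Ocri2Error):
    """Classifier training preconditions violated (labels, class counts)."""


class StratificationError(Ocri2Error):
    """A class is too small to split or stratify."""


class DegenerateTableError(Ocri2Error):
    """Contingency table has a zero marginal; the test is undefined."""


class TransformError(Ocri2Error):
    """One or more cases could not be transformed into peak features."""

    def __init__(self, message: str, case_ids: list[str] | None = None):
        super().__init__(message)
        self.case_ids = list(case_ids or [])
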