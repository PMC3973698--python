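"""Exception hierarchy.

Every error signal raised by the library derives from :class:`CrowdScoreError`,
so the command-line layer can catch one type and exit nonzero.
"""


class CrowdScoreError(Exception):
    """Base class for all crowdscore errors."""


class ValidationError(CrowdScoreError):
    """Malformed or inconsistent input data."""


class MissingColumnError(ValidationError):
    """A required column is absent from an input table."""


class DuplicateResponseIdError(ValidationError):
    """response_id values are not unique within a dataset."""


class EmptyNormativeSetError(CrowdScoreError):
    """Exclusion (or filtering) left a normative set with no members."""


class UnrepresentablePassageError(CrowdScoreError):
    """A passage has no in-vocabulary words in the semantic space."""


class RankDeficiencyError(CrowdScoreError):
    """Requested embedding dimensionality exceeds the achievable rank."""

    def __init__(self, requested: int, achievable: int):
        self.requested = requested
        self.achievable = achievable
        super().__init__(
            f"requested dimensionality {requested} exceeds achievable rank "
            f"{achievable}"
        )


class SmallClipError(CrowdScoreError):
    """One or more clips have too few responses for the requested operation."""


class FitConvergenceError(CrowdScoreError):
    """Nonlinear least squares failed to converge."""


class DegenerateCurveError(CrowdScoreError):
    """A curve is flat (or too short) and cannot constrain the fit."""


class ConstantScoresError(CrowdScoreError):
    """All scores identical: a rank correlation is undefined."""


class MissingStrataError(CrowdScoreError):
    """No stratum contains both contrast conditions."""
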