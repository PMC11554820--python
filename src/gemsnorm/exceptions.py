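"""Exception hierarchy.

Validation problems (malformed files, out-of-range inputs) are kept distinct
from computation problems (degenerate models, rank deficiency) so the CLI can
map them to stable exit codes.
"""


class GemsError(Exception):
    """Base class for all package errors."""


class ValidationError(GemsError):
    """Malformed or out-of-range input (file structure, score ranges, ...)."""


class SchemaError(ValidationError):
    """A file is structurally wrong (missing columns, no rows, bad header)."""


class ScoringError(GemsError):
    """A session cannot be scored (missing task, unknown task id, bad raw)."""


class ComputationError(GemsError):
    """A statistical operation cannot proceed on the given data."""


class DegenerateModelError(ComputationError):
    """A fitted model has zero residual variance and cannot support inference."""


class CollinearityError(ComputationError):
    """The design matrix is rank deficient."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design; collinear columns: " + ", ".join(self.columns)
        )
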