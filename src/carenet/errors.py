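"""Exception hierarchy for the carenet pipeline.

Every domain error derives from :class:`CareNetError` so the CLI can map any
pipeline failure to a nonzero exit code with a stage-labelled message.
"""


class CareNetError(Exception):
    """Base class for all carenet domain errors."""


class SchemaError(CareNetError):
    """A records file does not conform to the expected column schema."""


class RecordParseError(CareNetError):
    """A single data row could not be parsed; carries the 1-based row index."""

    def __init__(self, row: int, message: str):
        self.row = row
        super().__init__(f"row {row}: {message}")


class EmptyMatrixError(CareNetError):
    """Aggregation or filtering produced a matrix with nothing to analyze."""


class ZeroVarianceError(CareNetError):
    """A column with zero variance reached a correlation computation."""


class NotPositiveDefiniteError(CareNetError):
    """A matrix required to be positive (semi)definite is not."""


class ConvergenceError(CareNetError):
    """The graphical lasso solver failed to converge; carries diagnostics."""

    def __init__(self, message: str, n_iter: int, kkt_residual: float):
        self.n_iter = n_iter
        self.kkt_residual = kkt_residual
        super().__init__(
            f"{message} (sweeps={n_iter}, kkt_residual={kkt_residual:.3e})"
        )


class SyntheticModelError(CareNetError):
    """A requested synthetic ground-truth structure is invalid."""
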