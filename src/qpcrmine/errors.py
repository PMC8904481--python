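"""Exception hierarchy shared across the package.

Every module raises subclasses of :class:`QpcrMineError` so callers (and the
CLI) can trap package failures without catching unrelated exceptions.
"""


class QpcrMineError(Exception):
    """Base class for all package errors."""


class FormatError(QpcrMineError):
    """Input table malformed: missing column, bad header, wrong shape."""


class DuplicateRecordError(FormatError):
    """Two rows claim the same (sample, gene) observation."""


class ValueParseError(FormatError):
    """A cell that must be numeric is neither numeric nor a known sentinel."""


class ConfigError(QpcrMineError):
    """Invalid run configuration (unknown gene, bad base, bad alpha, ...)."""


class DesignError(QpcrMineError):
    """Experimental-design violation: empty cells, unbalanced data, n <= 0."""


class AlignmentError(QpcrMineError):
    """Two datasets that must share keys (replicates, rows) do not."""


class SingularityError(QpcrMineError):
    """A covariance matrix is singular and no regularization was requested."""
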