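"""Exception hierarchy.

``PoptrajError`` is the base for everything the library raises on bad input
or data; the CLI maps it to exit code 1 and anything else to exit code 2.
"""


class PoptrajError(Exception):
    """Base class for all errors raised by poptraj."""


class DataError(PoptrajError):
    """Invalid or inconsistent input data."""


class DimensionMismatchError(DataError):
    """Matrix/identifier dimensions disagree across layers."""


class MissingVelocityError(DataError):
    """The velocity layer is absent; it must be estimated upstream."""


class FitError(PoptrajError):
    """A model fit failed (non-finite data, collapsed component, Cholesky)."""


class GraphError(PoptrajError):
    """Degenerate geometry or invalid parameters in graph construction."""


class TrajectoryError(PoptrajError):
    """Path detection or pseudo-time assignment failed."""


class MetricError(PoptrajError):
    """An evaluation statistic is undefined for the given vectors."""


class ConfigError(PoptrajError):
    """Unknown or invalid configuration keys."""


class PipelineError(PoptrajError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"[{stage}] {message}")
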