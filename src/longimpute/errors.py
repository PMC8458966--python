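"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ``ConfigError`` -> 1, any other
``LongimputeError`` (or unexpected exception) -> 2.
"""


class LongimputeError(Exception):
    """Base class for all package errors."""


class InputError(LongimputeError):
    """A caller-supplied value violates an operation's precondition."""


class ConfigError(LongimputeError):
    """A configuration file or spec object is invalid."""


class ShapeError(InputError):
    """An array shape is incompatible with a network or operation."""


class UnsupportedContentError(InputError):
    """A file exists but does not hold the expected kind of image."""


class MetricUndefinedError(LongimputeError):
    """A segmentation metric is undefined for the given masks (e.g. empty)."""


class TrainingDivergenceError(LongimputeError):
    """A loss term became non-finite during optimisation."""

    def __init__(self, term: str, value: float):
        self.term = term
        self.value = value
        super().__init__(f"non-finite loss term {term!r}: {value!r}")


class CheckpointError(LongimputeError):
    """A weight checkpoint does not match the architecture it is loaded into."""


class DataError(LongimputeError):
    """A cohort or subject record is structurally unusable."""
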