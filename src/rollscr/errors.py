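"""Exception hierarchy shared across the package."""


class RollScrError(Exception):
    """Base class for all package errors."""


class FormatError(RollScrError, ValueError):
    """A delimited input file violates its documented schema."""


class ParameterError(RollScrError, ValueError):
    """An argument is outside its valid domain."""


class EstimationError(RollScrError, RuntimeError):
    """The likelihood cannot be maximised for the given histories."""


class PipelineError(RollScrError, RuntimeError):
    """A batch stage failed for every input."""
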