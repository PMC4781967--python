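"""Exception hierarchy shared across the pipeline.

All pipeline-raised errors derive from :class:`PipelineError` so callers can
distinguish expected input/configuration problems from genuine bugs.
"""


class PipelineError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(PipelineError):
    """A file does not conform to the documented tabular dialect."""


class ValidationError(PipelineError):
    """A file parses but violates a domain invariant (duplicate key, out-of-range value...)."""


class ConfigurationError(PipelineError):
    """A run-level precondition is unmet (too few subjects, missing group...)."""


class DegenerateInputError(PipelineError):
    """A statistic is undefined for this input (e.g. constant vector).

    Callers typically skip the offending probe/genus rather than abort the run.
    """
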