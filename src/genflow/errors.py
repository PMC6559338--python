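"""Exception hierarchy for the genflow engine.

Every error raised deliberately by the engine derives from
:class:`GenFlowError`, so callers (notably the CLI) can distinguish
engine-level failures from programming errors.
"""


class GenFlowError(Exception):
    """Base class for all genflow errors."""


class FormatError(GenFlowError):
    """A user-provided input file (readset, design, pairs, INI) is malformed."""


class ConfigError(GenFlowError):
    """A configuration parameter is missing or cannot be coerced."""


class DependencyError(GenFlowError):
    """Input resolution or DAG construction failed (unresolvable input,
    duplicate output producer, dependency cycle, unknown job)."""


class GenerationError(GenFlowError):
    """A step's job factory failed while generating jobs."""


class ValidationError(GenFlowError):
    """Pre-flight validation of a run failed (missing files or modules)."""
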