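"""Exception types shared across the pipeline."""


class StagewalkError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(StagewalkError, ValueError):
    """Invalid configuration (non-positive counts, missing seed, ...)."""


class FormatError(StagewalkError, ValueError):
    """Malformed on-disk data; message names the offending file (and line)."""


class DegenerateInputError(StagewalkError, ValueError):
    """Input too short / constant / empty for the requested operation."""


class NumericalDegeneracyError(StagewalkError, ArithmeticError):
    """A statistic is undefined on this input (e.g. zero variance everywhere)."""
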