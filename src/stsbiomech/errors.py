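"""Exception hierarchy shared by all pipeline stages.

The CLI maps these onto exit codes: config errors -> 2, data errors -> 3,
numerical failures -> 4.
"""


class STSBiomechError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(STSBiomechError, ValueError):
    """A caller supplied an argument outside its documented domain."""


class InvalidConfigError(STSBiomechError, ValueError):
    """A configuration value is inconsistent or out of range."""


class InvalidDataError(STSBiomechError, ValueError):
    """Input data violate a structural precondition (NaNs, shape, missing)."""


class NumericalFailureError(STSBiomechError, RuntimeError):
    """An iterative numerical procedure diverged or failed to converge."""
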