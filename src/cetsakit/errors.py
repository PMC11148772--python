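"""Exception hierarchy shared across the pipeline.

``exit_code`` is consumed by the command-line wrapper: 2 = validation,
3 = I/O, 4 = numerical failure.
"""


class CetsaError(Exception):
    """Base class for all cetsakit errors."""

    exit_code = 1


class ParameterError(CetsaError, ValueError):
    """A model parameter is outside its mathematical domain."""

    exit_code = 2


class ValidationError(CetsaError, ValueError):
    """Input data or configuration violates a structural contract."""

    exit_code = 2


class CurveInvalidError(CetsaError, ValueError):
    """A melting curve cannot be normalized (e.g. zero reference signal)."""

    exit_code = 2


class NotCorrectableError(CetsaError, ValueError):
    """Baseline correction is undefined for this curve (non-melter)."""

    exit_code = 2


class NumericalError(CetsaError, ArithmeticError):
    """A numerical operation failed (singular system, zero dispersion)."""

    exit_code = 4
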