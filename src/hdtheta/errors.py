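"""Exception hierarchy shared across the package."""


class HDThetaError(Exception):
    """Base class for all package-specific errors."""


class InvalidArgumentError(HDThetaError, ValueError):
    """An argument violates a documented precondition."""


class UndefinedMetricError(HDThetaError, ValueError):
    """A metric is mathematically undefined for the given input
    (e.g. normalising an all-zero tuning curve, selectivity of a silent unit)."""


class MissingMetricError(HDThetaError, ValueError):
    """Classification was requested with a required metric absent."""

    def __init__(self, name: str):
        super().__init__(f"cannot classify unit: missing metric {name!r}")
        self.name = name


class NotConvergedError(HDThetaError, RuntimeError):
    """Nonlinear fit failed from every starting point.

    Carries the best partial fit found, if any, in ``best_fit``.
    """

    def __init__(self, message: str, best_fit=None):
        super().__init__(message)
        self.best_fit = best_fit


class ParseError(HDThetaError, ValueError):
    """A session file violates the documented text dialect."""

    def __init__(self, path, line_no: int | None, message: str):
        loc = f"{path}:{line_no}" if line_no is not None else str(path)
        super().__init__(f"{loc}: {message}")
        self.path = path
        self.line_no = line_no
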