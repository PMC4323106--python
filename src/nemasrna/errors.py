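"""Exception hierarchy shared across the package."""


class NemasrnaError(Exception):
    """Base class for all package errors."""


class ParameterError(NemasrnaError, ValueError):
    """A parameter violates its documented range or relationship."""


class ContractError(NemasrnaError, ValueError):
    """An input violates an operation's precondition."""


class EmptyLibraryError(NemasrnaError, ValueError):
    """A library with zero reads where at least one is required."""


class PlacementError(NemasrnaError, RuntimeError):
    """A repeat specification could not be placed without overlap."""


class UndefinedRatioError(NemasrnaError, ZeroDivisionError):
    """A ratio whose denominator class is absent from the data."""


class UndefinedCorrelationError(NemasrnaError, ValueError):
    """Correlation requested on constant input."""
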