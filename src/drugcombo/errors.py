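"""Exception hierarchy shared by all drugcombo modules."""


class DrugComboError(Exception):
    """Base class for all package errors."""


class InvalidArgumentError(DrugComboError, ValueError):
    """An argument violates a precondition (non-positive dose, bad length, ...)."""


class OutOfDomainError(DrugComboError, ValueError):
    """A value lies outside the mathematical domain of an operation (fa in {0, 1})."""


class InsufficientDataError(DrugComboError, ValueError):
    """Fewer usable observations than the operation requires."""


class DegenerateDesignError(DrugComboError, ValueError):
    """The design matrix is singular (e.g. all doses identical)."""


class NonMonotoneDataError(DrugComboError, ValueError):
    """Fitted slope is non-positive; data do not describe an increasing dose-effect."""


class UnitMismatchError(DrugComboError, ValueError):
    """Quantities with different concentration units were combined."""


class InvalidPlateError(DrugComboError, ValueError):
    """Plate data lack a signal window or required control/blank groups."""


class SchemaError(DrugComboError, ValueError):
    """An input table is missing required columns or has malformed values."""


class NumericalError(DrugComboError, ArithmeticError):
    """A numerical routine (root finding) failed to converge."""


class PipelineError(DrugComboError, RuntimeError):
    """A pipeline stage failed; message is tagged with the stage name."""
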