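"""Exception hierarchy for the sensor-array pipeline."""


class InhibisenseError(Exception):
    """Base class for all package-specific errors."""


class DomainError(InhibisenseError, ValueError):
    """A numeric argument is outside its physical domain (e.g. c <= 0)."""


class RangeError(InhibisenseError, ValueError):
    """A requested coordinate lies outside the measured sweep."""


class StructureError(InhibisenseError, ValueError):
    """A data container is malformed (missing branch, wrong dimensions)."""


class RegistryError(InhibisenseError, LookupError):
    """Unknown bacterium, pollutant, group or class index."""


class SchemaError(InhibisenseError, ValueError):
    """A tabular file is missing or mislabels a required column."""


class ParseError(InhibisenseError, ValueError):
    """A tabular file holds a non-numeric cell; carries the row index."""


class IntegrityError(InhibisenseError, RuntimeError):
    """A packaged resource failed its self-consistency checks."""


class FitDomainError(InhibisenseError, ValueError):
    """An impedance sweep does not bracket the information the fit needs."""


class FitError(InhibisenseError, RuntimeError):
    """Nonlinear refinement failed to converge; carries initial estimates."""

    def __init__(self, message, initial_estimates=None):
        super().__init__(message)
        self.initial_estimates = initial_estimates


class TrainingError(InhibisenseError, RuntimeError):
    """Levenberg-Marquardt training aborted; carries diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class DataError(InhibisenseError, ValueError):
    """Inconsistent dataset (empty group, mismatched lengths, ...)."""
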