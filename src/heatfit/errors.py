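"""Exception hierarchy used across the package."""


class HeatfitError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(HeatfitError, ValueError):
    """A thermodynamic parameter or concentration is out of its valid domain."""


class InvalidComparisonError(HeatfitError, ValueError):
    """Two quantities with incompatible units or provenance were compared."""


class InvalidDesignError(HeatfitError, ValueError):
    """A titration design is inconsistent with the requested analysis."""


class SolverFailureError(HeatfitError, RuntimeError):
    """The equilibrium root solver could not bracket or converge; carries diagnostics."""


class OracleFailureError(HeatfitError, RuntimeError):
    """The independent verification solver failed to converge."""


class FitFailureError(HeatfitError, RuntimeError):
    """No optimization start converged; carries per-start diagnostics."""
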