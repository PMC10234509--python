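"""Exception types shared across the package."""


class MyofeError(Exception):
    """Base class for all package-specific errors."""


class InvalidDeformationError(MyofeError):
    """Raised for kinematically inadmissible deformation states (J <= 0,
    non-unit fiber direction beyond tolerance, inverted elements)."""


class ConvergenceError(MyofeError):
    """Raised when an iterative solve fails (series-increment root find,
    lateral-stretch solve, explicit-step divergence)."""


class ConfigurationError(MyofeError):
    """Raised for inconsistent user configuration (bad parameter values,
    missing/empty boundary sets, unpaired cohesive facets)."""
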