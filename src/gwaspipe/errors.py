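"""Exception hierarchy.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
NumericalError -> 4; anything else -> 1.
"""


class GwaspipeError(Exception):
    """Base class for all package errors."""


class ConfigError(GwaspipeError):
    """Invalid configuration (unknown keys, bad parameter values)."""


class DataError(GwaspipeError):
    """Malformed or inconsistent input data."""


class NumericalError(GwaspipeError):
    """Numerical failure (non-convergence, undefined quantity)."""


class LdInfeasibleError(NumericalError):
    """Requested LD level is unattainable for the given allele frequencies."""

    def __init__(self, r2_target: float, r2_max: float, p: float, q: float):
        self.r2_target = r2_target
        self.r2_max = r2_max
        super().__init__(
            f"target r2={r2_target:.4g} infeasible for allele frequencies "
            f"p={p:.4g}, q={q:.4g}; maximum attainable r2={r2_max:.6g}"
        )


class SeparationError(NumericalError):
    """Complete or quasi-complete separation in a logistic model."""
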