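"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError -> 2,
ConvergenceError -> 3, OSError -> 4.
"""


class ScaffoldError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(ScaffoldError, ValueError):
    """Invalid user-supplied parameter or inconsistent input."""


class AchievableRangeError(ValidationError):
    """Requested porosity lies outside what the discretized field can realize."""

    def __init__(self, target: float, lo: float, hi: float):
        self.target = target
        self.achievable = (lo, hi)
        super().__init__(
            f"target void fraction {target:.4g} outside achievable range "
            f"[{lo:.4g}, {hi:.4g}] at this resolution"
        )


class ConvergenceError(ScaffoldError, RuntimeError):
    """Iterative calibration failed to reach the requested tolerance."""

    def __init__(self, message: str, bracket=None):
        self.bracket = bracket
        super().__init__(message)


class MeshError(ScaffoldError, ValueError):
    """Mesh fails a structural requirement (e.g. not watertight)."""


class MetadataError(ScaffoldError, ValueError):
    """Image-stack metadata sidecar missing or incomplete."""
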