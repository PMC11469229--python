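"""Exception types raised across the package."""


class MarrowMechError(Exception):
    """Base class for all package-specific errors."""


class InvalidSpecError(MarrowMechError, ValueError):
    """A vessel specification or run configuration is inconsistent."""


class MeshError(MarrowMechError, ValueError):
    """A mesh violates a structural invariant (inverted cells, bad sets...)."""


class SelfIntersectionError(MeshError):
    """A surface operation produced self-intersecting triangles."""

    def __init__(self, pairs):
        self.pairs = list(pairs)
        preview = ", ".join(f"({a},{b})" for a, b in self.pairs[:8])
        more = "" if len(self.pairs) <= 8 else f" ... ({len(self.pairs)} pairs total)"
        super().__init__(f"surface self-intersection between triangle pairs: {preview}{more}")


class InvertedElementError(MarrowMechError, ValueError):
    """A deformation state has non-positive Jacobian (det F <= 0)."""


class MaterialError(MarrowMechError, ValueError):
    """Invalid material parameters (e.g. nu == 0.5 exactly)."""


class ConvergenceError(MarrowMechError, RuntimeError):
    """The nonlinear static solve failed to converge."""

    def __init__(self, message, residual=None):
        self.residual = residual
        super().__init__(message)


class StabilityError(MarrowMechError, RuntimeError):
    """The explicit time integration went unstable (energy blow-up or NaN)."""


class PostprocessError(MarrowMechError, ValueError):
    """Invalid input to a stress-statistics operation."""
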