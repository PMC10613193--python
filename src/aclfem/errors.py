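"""Exception hierarchy for the pipeline."""


class AclFemError(Exception):
    """Base class for all package errors."""


class DomainError(AclFemError, ValueError):
    """A scalar argument is outside its physical domain."""


class ValidationError(AclFemError, ValueError):
    """A structured input violates an invariant."""


class GeometryError(AclFemError):
    """Solids do not intersect / pierce as required."""


class MeshingError(AclFemError):
    """Mesh generation failed (e.g. path shorter than one element)."""


class InvertedElementError(AclFemError):
    """An element has non-positive volume / Jacobian."""

    def __init__(self, element_id: int, volume: float):
        self.element_id = element_id
        self.volume = volume
        super().__init__(
            f"element {element_id} has non-positive volume {volume:.3e}"
        )


class InvertedConfigurationError(AclFemError):
    """det F <= 0: the deformation locally inverts material."""


class AssemblyError(AclFemError):
    """Model assembly failed (e.g. unpaired tie nodes)."""


class ConvergenceError(AclFemError):
    """Newton iteration failed to converge; carries the residual history."""

    def __init__(self, message: str, residual_history=None):
        self.residual_history = list(residual_history or [])
        super().__init__(message)


class GimbalLockError(AclFemError):
    """Euler-angle decomposition is degenerate for this pose."""


class PipelineError(AclFemError):
    """End-to-end run failed; names the stage, model and angle."""

    def __init__(self, stage: str, model: str, angle, cause: Exception):
        self.stage = stage
        self.model = model
        self.angle = angle
        self.cause = cause
        super().__init__(
            f"pipeline stage '{stage}' failed for model '{model}' "
            f"at flexion angle {angle}: {cause}"
        )
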