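"""Exception hierarchy for cathsim."""


class CathsimError(Exception):
    """Base class for all cathsim errors."""


class ValidationError(CathsimError, ValueError):
    """Invalid user-supplied parameter or configuration value."""


class MeshFormatError(CathsimError, ValueError):
    """File could not be parsed as the requested mesh format."""


class EmptyMeshError(MeshFormatError):
    """Mesh contains no (non-degenerate) triangles."""


class SingularSystemError(CathsimError, ValueError):
    """The stationarity matrix is not positive definite.

    Carries ``null_direction``, a unit vector along the (near-)null space,
    to help diagnose which degree of freedom is unconstrained.
    """

    def __init__(self, message: str, null_direction=None):
        super().__init__(message)
        self.null_direction = null_direction


class SetupError(CathsimError, ValueError):
    """Simulation setup is inconsistent (e.g. catheter base outside the vessel)."""


class StateError(CathsimError, ValueError):
    """Operation not permitted in the current catheter state (e.g. over-withdrawal)."""
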