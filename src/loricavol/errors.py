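"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input violates a documented precondition."""


class NoObjectError(ValidationError):
    """A mask or stack contains no foreground."""


class WallGeometryError(ValidationError):
    """Inner lorica profile exceeds the outer one: no physical wall."""


class MeshNotClosedError(ValueError):
    """A surface mesh component is not watertight."""

    def __init__(self, n_open_edges: int):
        self.n_open_edges = n_open_edges
        super().__init__(
            f"mesh component is not watertight: {n_open_edges} open edge(s)"
        )


class StageClassificationError(ValidationError):
    """Contradictory oral-primordium features."""


class PackingError(RuntimeError):
    """Rejection sampling failed to place all requested granules."""
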