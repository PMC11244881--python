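"""Exception types shared across the package."""


class ValidationError(ValueError):
    """Input violates a precondition (shape, range, calibration...)."""


class GeometryError(RuntimeError):
    """A geometric construction failed (e.g. ray misses the boundary)."""


class InsufficientDataError(ValueError):
    """Too few data points to compute the requested quantity."""
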