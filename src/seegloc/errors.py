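"""Typed exceptions shared across the package."""


class SeeglocError(Exception):
    """Base class for all package errors."""


class ValidationError(SeeglocError, ValueError):
    """An input violated a documented invariant (bad value, bad schema)."""


class GridMismatchError(ValidationError):
    """Two volumes expected on the same grid differ in shape or affine."""


class ResectionError(SeeglocError):
    """Resection-mask computation could not produce a usable mask."""
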