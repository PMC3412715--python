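"""Exception hierarchy shared by all voxtile modules."""


class VoxtileError(Exception):
    """Base class for all voxtile errors."""


class EmptyObjectError(VoxtileError):
    """Raised when an operation requires a non-empty spatial domain."""


class NoValuesError(VoxtileError):
    """Raised when a value query hits a domain-only (value-less) object."""


class GeometryError(VoxtileError):
    """Base class for sectioning-geometry errors."""


class DegenerateUpError(GeometryError):
    """The up vector is parallel to the viewing direction (up-is-up mode)."""


class DegenerateLineError(GeometryError):
    """The two fixed points of fixed-line mode coincide."""


class ProtocolError(VoxtileError):
    """Malformed or unsatisfiable tile-protocol request."""


class FormatError(VoxtileError):
    """Corrupt or unsupported file content."""


class BlockShapeError(VoxtileError):
    """Block shape violates the filesystem-block alignment rule."""
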