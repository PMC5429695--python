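"""Exception hierarchy shared across the package."""


class CohdocError(Exception):
    """Base class for all package errors."""


class ParseError(CohdocError):
    """A coordinate or data file could not be parsed."""


class FormatError(CohdocError):
    """An unknown or unsupported file format was requested."""


class SelectionError(CohdocError):
    """An atom/chain/residue selection referenced something absent."""


class SequenceError(CohdocError):
    """A chain holds no polymer residues or a sequence operation failed."""


class GeometryError(CohdocError):
    """Degenerate or mismatched coordinates in a geometric operation."""


class SymmetryError(CohdocError):
    """Internal-symmetry analysis could not be completed."""


class FingerprintError(CohdocError):
    """A sequence could not be placed in the reference dockerin frame."""


class ProtocolError(CohdocError):
    """An ITC titration protocol is physically inconsistent."""


class GenerationError(CohdocError):
    """A synthetic fixture could not be built (e.g. steric self-clash)."""
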