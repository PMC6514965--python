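"""Exception hierarchy for capscan."""


class CapscanError(Exception):
    """Base class for all capscan errors."""


class PDBParseError(CapscanError):
    """A PDB record could not be parsed."""


class PQRParseError(CapscanError):
    """A PQR record could not be parsed."""


class GeometryError(CapscanError):
    """A geometric precondition (degenerate axis, zero mass, ...) failed."""


class ConvergenceError(CapscanError):
    """An iterative solver did not reach its tolerance."""


class OverlapError(CapscanError):
    """Two rigid bodies overlap below the minimum allowed separation."""
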