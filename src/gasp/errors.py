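"""Exception hierarchy."""


class GaspError(Exception):
    """Base class for all package errors."""


class InputError(GaspError, ValueError):
    """Invalid user-supplied value (bad residue, unknown label, ...)."""


class ContractError(GaspError, RuntimeError):
    """Objects combined in a way the API forbids (e.g. mismatched reference)."""


class AnnotationParseError(GaspError, ValueError):
    """An annotation file could not be parsed at all."""


class NewickParseError(GaspError, ValueError):
    """Malformed Newick input."""


class UndefinedDistanceError(GaspError, ValueError):
    """A pairwise distance is undefined (no comparable columns)."""
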