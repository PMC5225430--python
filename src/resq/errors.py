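"""Exception hierarchy."""


class ResqError(Exception):
    """Base class for all package errors."""


class PDBParseError(ResqError):
    """Malformed or unusable PDB input."""


class InsufficientOverlapError(ResqError):
    """Fewer than three shared residues between two structures."""


class SchemaError(ResqError):
    """Feature table column does not match the feature schema."""


class FormatError(ResqError):
    """Malformed tabular or alignment input."""


class InferenceError(ResqError):
    """Internal inconsistency in the graphical model (tree invariants)."""


class UndefinedValueError(ResqError):
    """A requested metric is undefined for the given inputs."""
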