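"""Exception hierarchy shared across the package."""


class Rna3wjError(Exception):
    """Base class for all package errors."""


class StructureParseError(Rna3wjError):
    """Malformed dot-bracket or sequence input."""


class UnsupportedTopologyError(Rna3wjError):
    """Topology outside the supported scope (e.g. junctions with more than three branches)."""


class DegenerateGeometryError(Rna3wjError):
    """Geometric operation on degenerate input (zero vectors, collinear anchors, ...)."""


class UnresolvableNodeError(Rna3wjError):
    """A tree node has no resolvable C4' coordinates."""


class ContractError(Rna3wjError):
    """Model / featurization contract mismatch (e.g. checkpoint layout fingerprint)."""


class TrainingDivergedError(Rna3wjError):
    """Loss became non-finite during optimization."""
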