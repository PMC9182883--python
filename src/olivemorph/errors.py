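"""Exception hierarchy shared across the package."""


class OliveMorphError(Exception):
    """Base class for all package-specific errors."""


class MeshFormatError(OliveMorphError):
    """A mesh file could not be parsed, or was empty after cleaning."""


class MeshPreconditionError(OliveMorphError):
    """A mesh does not satisfy the geometric precondition of an operation
    (e.g. volume requested on a non-watertight surface)."""


class ParameterError(OliveMorphError):
    """An argument is outside its documented domain."""


class DegenerateObjectError(OliveMorphError):
    """A segmented 2D object is too small or too thin to measure."""


class DataError(OliveMorphError):
    """Tabular inputs violate a contract (missing traits, disjoint sample
    ids, groups too small for the requested statistic)."""
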