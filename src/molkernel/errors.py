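"""Exception types shared across the package."""


class MolkernelError(Exception):
    """Base class for all package-specific errors."""


class FormatError(MolkernelError):
    """A structure file could not be parsed in the requested format."""


class InconsistentMoleculeError(MolkernelError):
    """A covalently bonded group does not have the expected atom count."""


class DifferentMoleculeError(MolkernelError):
    """A bonded group is not graph-isomorphic to the reference molecule."""


class ParameterMismatchError(MolkernelError):
    """Descriptors built with incompatible parameters were combined."""


class InvalidSetError(MolkernelError):
    """A structure set violates the preconditions of the adapted kernel."""


class KernelIntegrityError(MolkernelError):
    """A kernel matrix failed a positivity / symmetry requirement."""


class DegenerateStructureError(MolkernelError):
    """A structure produced a degenerate (zero self-similarity) kernel entry."""
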