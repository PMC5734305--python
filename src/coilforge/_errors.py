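"""Exception hierarchy.

Everything raised deliberately by coilforge derives from CoilforgeError so CLI
and library users can catch one type.
"""


class CoilforgeError(Exception):
    """Base class for all coilforge errors."""


class DomainError(CoilforgeError, ValueError):
    """A numeric argument is outside its mathematical domain."""


class ValidationError(CoilforgeError, ValueError):
    """An assembly specification violates the build rules."""


class BuildError(CoilforgeError):
    """Backbone construction failed."""


class SidechainError(CoilforgeError):
    """Side-chain placement failed or was mis-requested."""


class AnalysisError(CoilforgeError):
    """A structure does not satisfy the preconditions of an analysis."""


class ScoringError(CoilforgeError):
    """Force-field parameters are missing or a model cannot be scored."""


class OptimizationError(CoilforgeError):
    """An optimization request violates its restrictions."""


class PdbFormatError(CoilforgeError):
    """A PDB file could not be parsed or written within format limits."""
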