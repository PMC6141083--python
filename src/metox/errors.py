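"""Exception hierarchy.  All package errors derive from MetoxError so
callers can catch broadly; subclasses mark the contract that was violated.
"""


class MetoxError(Exception):
    """Base class for all package errors."""


class PDBParseError(MetoxError):
    """A PDB record could not be parsed; the message names the line."""


class PDBFormatError(MetoxError):
    """A structure cannot be encoded in fixed-column PDB fields."""


class TopologyError(MetoxError):
    """Frames of a trajectory disagree in atom count or ordering, or a
    chain is disconnected."""


class SelectionError(MetoxError):
    """An atom selection is empty, overlapping where disjointness is
    required, or otherwise unusable."""


class GrammarError(SelectionError):
    """A selection expression does not parse under the mini-grammar."""


class ParameterizationError(MetoxError):
    """An atom could not be resolved in a parameter table."""


class IncompleteResidueError(MetoxError):
    """A residue is missing atoms required by an operation."""


class GeometryError(MetoxError):
    """Degenerate geometry (coincident atoms, NaN coordinates)."""


class DomainError(MetoxError):
    """An argument is outside the operation's mathematical domain."""


class SamplerHealthError(MetoxError):
    """A Monte Carlo sampler's acceptance rate collapsed."""


class NonOverlapError(MetoxError):
    """Bennett's equation has no root in any reasonable bracket: forward
    and backward work distributions do not overlap.  Use more windows."""


class InstabilityError(MetoxError):
    """The integrator blew up; reduce the time step."""


class SpecError(MetoxError):
    """A generator or model specification is internally inconsistent."""


class ConfigError(MetoxError):
    """A report/experiment configuration is invalid."""
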