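"""Exception hierarchy shared across the package."""


class BindsurfError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(BindsurfError):
    """A coordinate record could not be parsed; message names the line number."""


class ModelIndexError(BindsurfError, IndexError):
    """Requested model number is absent from a (possibly multi-model) PDB file."""


class SequenceError(BindsurfError, ValueError):
    """Invalid amino-acid sequence text."""


class DegenerateGeometryError(BindsurfError):
    """Coinciding atoms of equal radius make the surface ill-defined."""


class ChainLookupError(BindsurfError, KeyError):
    """A chain identifier is not present in the structure."""


class CriteriaError(BindsurfError, ValueError):
    """Pose-selection criteria cannot be applied to the given pose."""


class CoordinateError(BindsurfError):
    """A residue required for geometric ordering lacks coordinates."""


class DegenerateDesignError(BindsurfError):
    """Every hot spot mapped to the spacer residue; no anchor positions remain."""


class FitError(BindsurfError):
    """A kinetic fit failed (no signal, too few points, or no convergence)."""


class DataError(BindsurfError, ValueError):
    """Input table or trace violates a precondition."""


class ConfigError(BindsurfError, ValueError):
    """Pipeline configuration failed schema validation."""
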