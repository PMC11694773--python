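"""Exception hierarchy shared across the pipeline stages."""


class MechanomicsError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(MechanomicsError, ValueError):
    """A tunable parameter is outside its admissible range."""


class GeometryError(MechanomicsError, ValueError):
    """Shapes, spacings or coordinate frames of two inputs disagree."""


class FormatError(MechanomicsError, ValueError):
    """An input encodes values outside the documented vocabulary."""


class EmptyInputError(MechanomicsError, ValueError):
    """An operation received an input with no voxels/rows to work on."""


class UndefinedRatioError(MechanomicsError, ZeroDivisionError):
    """A normalising volume or area is zero, the ratio is undefined."""


class MaterialError(MechanomicsError, ValueError):
    """Density-to-modulus mapping produced a non-physical modulus."""


class SolverError(MechanomicsError, RuntimeError):
    """The linear system could not be solved."""


class ConvergenceError(SolverError):
    """Iterative solver exhausted its iteration budget."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class ScalingError(MechanomicsError, ValueError):
    """Force-ratio strain scaling is undefined (non-positive resultant)."""


class OptimizationError(MechanomicsError, ValueError):
    """Load optimisation cannot proceed (e.g. zero median strain)."""


class PoseError(MechanomicsError, ValueError):
    """Section pose is not a proper rigid transform."""


class DomainError(MechanomicsError, ValueError):
    """A value lies outside the physical domain of the quantity."""


class ConsistencyError(MechanomicsError, KeyError):
    """Cross-referenced identifiers (e.g. barcodes) do not match."""


class EmptyGroupError(MechanomicsError, ValueError):
    """A requested group/region contains no members."""


class GroupSizeError(MechanomicsError, ValueError):
    """A group is too small for the requested statistic."""


class NormalizationError(MechanomicsError, ValueError):
    """Size-factor estimation is impossible on this count matrix."""


class DesignError(MechanomicsError, ValueError):
    """The experimental design does not support the requested test."""


class SpecError(MechanomicsError, ValueError):
    """A synthetic-data specification is internally inconsistent."""
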