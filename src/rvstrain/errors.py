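"""Exception hierarchy for rvstrain."""


class RVStrainError(Exception):
    """Base class for all rvstrain errors."""


class ObjParseError(RVStrainError):
    """A Wavefront OBJ record could not be parsed; message names file and line."""


class MeshValidationError(RVStrainError):
    """A mesh violates a geometric invariant (open surface, degenerate faces...)."""


class SeriesError(RVStrainError):
    """A frame series violates topology-constancy or ordering invariants."""


class AxisError(RVStrainError):
    """The long axis of a mesh could not be determined."""


class StrainError(RVStrainError):
    """Contour construction or strain computation failed."""


class ConfigError(RVStrainError):
    """A generator or pipeline configuration is invalid."""


class SchemaError(RVStrainError):
    """A tabular input is missing required columns or contains illegal values."""


class StatsError(RVStrainError):
    """A statistical routine received inadmissible input or failed to converge."""
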