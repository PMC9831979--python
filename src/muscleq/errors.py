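"""Exception hierarchy for muscleq."""


class MuscleQError(Exception):
    """Base class for all muscleq errors."""


class GeometryError(MuscleQError):
    """Phantom anatomy does not fit the voxel grid, or a header carries no usable spacing."""


class IncompatibilityError(MuscleQError):
    """Fat, water and mask volumes do not share one grid/spacing."""


class DataError(MuscleQError):
    """Voxel data violates basic assumptions (non-finite or negative intensities)."""


class InputError(MuscleQError, ValueError):
    """An operation was called with arguments outside its contract."""


class PlacementError(MuscleQError):
    """A phantom fat clump could not be placed after bounded retries."""


class ConfigurationError(MuscleQError):
    """Unknown profile or invalid pipeline configuration."""


class IntegrityError(MuscleQError):
    """A packaged fixture failed its checksum."""
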