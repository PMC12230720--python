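"""Exception types shared across the package."""


class EmfitError(Exception):
    """Base class for all package errors."""


class MapFormatError(EmfitError, ValueError):
    """A volume file is malformed; the message names the offending field."""


class StructureFormatError(EmfitError, ValueError):
    """A coordinate file has no usable polymer content or is malformed."""


class ParameterError(EmfitError, ValueError):
    """An argument is outside its valid range."""


class DegenerateMapError(EmfitError, ValueError):
    """A map has no signal left to work with (all voxels at/below threshold)."""


class ClassificationError(EmfitError, ValueError):
    """A chain cannot be assigned a molecule kind without user override."""


class PlacementError(EmfitError, RuntimeError):
    """The synthetic-layout sampler could not satisfy its spacing constraint."""


class FitFailure(EmfitError, RuntimeError):
    """No finite-scoring pose could be found for a chain."""
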