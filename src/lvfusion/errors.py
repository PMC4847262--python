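"""Exception hierarchy shared across the package."""


class LVFusionError(Exception):
    """Base class for all lvfusion errors."""


class InvalidGeometryError(LVFusionError):
    """Degenerate or non-simple geometric input (e.g. <3 distinct polygon points)."""


class NoIntersectionError(LVFusionError):
    """Cutting plane is parallel to the contour's plane."""


class MissingChordError(LVFusionError):
    """A cut yielded fewer than two intersection points; no chord can be formed."""


class EmptyRegionError(LVFusionError):
    """Clipping produced an empty region."""


class InvalidObliquityError(LVFusionError):
    """Obliquity angle outside [0, pi/2)."""


class DecompositionError(LVFusionError):
    """SAX/LAX chunk decomposition failed (message names the offending slice)."""


class DegenerateChunkError(LVFusionError):
    """Chunk with a zero denominator (no usable diameters)."""


class ConfigurationError(LVFusionError):
    """Missing or inconsistent configuration (e.g. unknown slice extent)."""


class InvalidPhantomError(LVFusionError):
    """Phantom specification violates its invariants (e.g. not star-shaped)."""


class ContourFileError(LVFusionError):
    """Contour interchange file failed schema validation."""
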