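"""Exception hierarchy shared across the scanner pipeline."""


class Disc3DError(Exception):
    """Base class for all errors raised by this package."""


class InvalidParameterError(Disc3DError, ValueError):
    """A parameter is outside its documented domain."""


class InvalidInputError(Disc3DError, ValueError):
    """Input data violate a precondition (shape, emptiness, ordering)."""


class DegenerateGeometryError(Disc3DError, ValueError):
    """A geometric quantity (e.g. a projective scale) is undefined."""


class CalibrationError(Disc3DError, RuntimeError):
    """Stack calibration failed (e.g. too few target features detected)."""


class ConfigError(Disc3DError, ValueError):
    """A pipeline configuration file is malformed; message names the key."""
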