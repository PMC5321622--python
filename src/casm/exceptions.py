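"""Exception hierarchy. Everything raised by casm derives from CasmError."""


class CasmError(Exception):
    """Base class for all casm errors."""


class RegistryError(CasmError, ValueError):
    """Invalid landmark registry or landmark definition."""


class PhaseOrderingError(CasmError, ValueError):
    """Phase boundary frames violate oral < pharyngeal onset < offset."""


class FrameRangeError(CasmError, ValueError):
    """A phase boundary falls outside the series' frame range."""


class MissingPhaseError(CasmError, KeyError):
    """Requested swallow phase is not labeled on the series."""


class TrackerFormatError(CasmError, ValueError):
    """Tracker text file violates the dialect (column count, header)."""


class TrackerParseError(CasmError, ValueError):
    """Non-numeric cell in a tracker data row."""


class FrameOrderError(CasmError, ValueError):
    """Frame column of a tracker file is not strictly increasing."""


class CompileCollisionError(CasmError, ValueError):
    """Duplicate (video, rater, trial, frame, landmark) key while compiling."""


class TPSFormatError(CasmError, ValueError):
    """TPS record malformed or landmark count mismatch."""


class DegenerateShapeError(CasmError, ValueError):
    """Shape has (near-)zero centroid size; superimposition undefined."""


class ShapeMismatchError(CasmError, ValueError):
    """Landmark counts of two configurations disagree."""


class SampleSizeError(CasmError, ValueError):
    """Too few shapes for the requested ordination."""


class ClassSizeError(CasmError, ValueError):
    """A discriminant group has fewer than the minimum members."""


class LabelError(CasmError, ValueError):
    """Classifier labels are not two-class."""


class GroupError(CasmError, KeyError):
    """Unknown or empty functional landmark group."""


class RatingSizeError(CasmError, ValueError):
    """Rating matrix smaller than 2 targets x 2 raters."""


class CoverageError(CasmError, ValueError):
    """Compiled table lacks data for a requested rater/trial comparison."""


class ConfigError(CasmError, ValueError):
    """Run configuration contains unknown or invalid keys."""
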