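"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`EcdynError`
so callers can catch one type at a pipeline boundary.  Subclasses map onto the
distinct failure modes of the public operations (parsing, selection, model
construction, numerical stability, configuration).
"""


class EcdynError(Exception):
    """Base class for all errors raised by ecdyn."""


class ParseError(EcdynError):
    """A file or table could not be parsed (message names the offending line)."""


class EmptyInputError(EcdynError):
    """A structure or trajectory contained no usable atoms/frames."""


class TopologyError(EcdynError):
    """Topology and trajectory disagree (e.g. atom-count mismatch)."""


class FormatError(EcdynError):
    """Unknown or unreadable file format."""


class SelectionError(EcdynError):
    """An atom selection is empty, malformed, or inconsistent with its target."""


class ArgumentError(EcdynError):
    """Invalid argument combination (bad window/offset, unknown label, ...)."""


class SequenceError(EcdynError):
    """An amino-acid sequence contains letters outside the standard alphabet."""


class SpecError(EcdynError):
    """An inconsistent construct specification."""


class GeometryError(EcdynError):
    """Degenerate geometry (e.g. collinear superposition selection)."""


class ModelError(EcdynError):
    """An invalid harmonic-network model (disconnected graph, extra null modes)."""


class StabilityError(EcdynError):
    """Numerical blow-up of an explicit integrator."""


class RankError(EcdynError):
    """More principal components requested than the positive spectrum provides."""


class DataError(EcdynError):
    """Non-finite or otherwise unusable numerical data."""


class ConsistencyError(EcdynError):
    """Inputs that must share a common atom/residue table do not."""


class ConfigError(EcdynError):
    """Invalid run configuration."""


class AmbiguityError(EcdynError):
    """A geometric classification has no well-defined answer."""
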