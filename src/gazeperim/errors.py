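"""Exception hierarchy for gazeperim."""


class GazePerimError(Exception):
    """Base class for all gazeperim errors."""


class ConfigError(GazePerimError, ValueError):
    """Invalid configuration (non-positive duration/rate, bad weights, ...)."""


class SpecificationError(GazePerimError, ValueError):
    """Unknown or invalid scotoma specification."""


class MalformedRecordError(GazePerimError, ValueError):
    """Tracking record with inconsistent sequence lengths or non-finite values."""


class ContaminationError(GazePerimError, ValueError):
    """A scotoma-condition trial leaked into the normative (no-loss) pool."""


class InsufficientOverlapError(GazePerimError, ValueError):
    """Too few commonly-sampled cells to compare two visual field maps."""


class SchemaError(GazePerimError, ValueError):
    """Trial/map file violates the on-disk schema."""
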