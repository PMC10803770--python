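"""Exception types shared across the pipeline stages."""


class EradScreenError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(EradScreenError):
    """Invalid simulation or pipeline configuration."""


class SchemaError(EradScreenError):
    """An input table is missing required columns."""


class IntegrityError(EradScreenError):
    """An input table violates a uniqueness or key constraint."""


class TrainingError(EradScreenError):
    """The training-label set cannot support a model fit."""


class StageError(EradScreenError):
    """A pipeline stage failed; the message names the stage and record."""
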