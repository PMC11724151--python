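"""Validation errors raised while reading simulation inputs.

Each failure mode gets its own class so callers (and the CLI) can report
precisely what was wrong with an input file without string matching.
"""


class ValidationError(ValueError):
    """Base class for all input-validation failures."""


class MissingInputError(ValidationError):
    """A referenced file or directory does not exist or is empty."""


class UnknownKeyError(ValidationError):
    """A configuration or species file contains an unrecognised key."""


class ValueParseError(ValidationError):
    """A value could not be parsed into its declared type, or violates a
    bound (e.g. ``timesteps,0``) or enum (e.g. an unknown reproduction
    model)."""


class MissingKeyError(ValidationError):
    """A required key (configuration path, temperature file) is absent."""


class SpeciesParameterError(ValidationError):
    """Species trait values are inconsistent (inverted niche limits,
    negative mass, mortality outside [0, 1], ...)."""


class EnvironmentShapeError(ValidationError):
    """Environment layers disagree in grid shape or series length."""
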