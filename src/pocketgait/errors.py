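"""Exception hierarchy for the gait pipeline.

Every error raised by the package derives from :class:`PocketGaitError`, so
callers (including the CLI) can distinguish pipeline failures from bugs.
Input/format problems and computation problems are separated because the CLI
maps them to different exit codes.
"""


class PocketGaitError(Exception):
    """Base class for all package errors."""


class InputError(PocketGaitError):
    """Problems with user-supplied inputs (files, tables, metadata)."""


class FormatError(InputError):
    """Malformed file: missing columns, non-monotone time, bad values."""


class TooShortError(InputError):
    """Recording shorter than the minimum usable duration."""


class ValidationError(InputError):
    """A value violates a documented domain invariant."""


class ComputationError(PocketGaitError):
    """The method could not be run on otherwise well-formed input."""


class ParameterError(ComputationError):
    """An algorithm parameter is out of its admissible range."""


class ContractError(ComputationError):
    """Mismatched intermediate products (e.g. series of unequal length)."""


class InsufficientEventsError(ComputationError):
    """Too few gait events detected to segment any stride."""


class DegenerateInputError(ComputationError):
    """Statistically degenerate input (e.g. all x identical)."""


class CannotInitializeError(ComputationError):
    """Orientation cannot be initialised (e.g. all-zero accelerometer)."""
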