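"""Exception hierarchy for scmseg.

Every error raised by the library derives from :class:`ScmsegError`, so
callers (and the CLI) can distinguish configuration problems from data
problems with a single ``except`` clause.
"""


class ScmsegError(Exception):
    """Base class for all scmseg errors."""


class ConfigError(ScmsegError, ValueError):
    """A configuration value violates its documented invariants."""


class DataError(ScmsegError, ValueError):
    """An input image, mask or file is malformed for the requested operation."""


class ShapeMismatchError(DataError):
    """Two arrays that must share a shape do not."""


class PlacementError(ScmsegError, RuntimeError):
    """Rejection sampling could not place the requested objects.

    Signals an over-dense configuration: the frame cannot geometrically
    hold ``n`` disks at the requested minimum separation, or the sampler
    exhausted its attempt budget trying.
    """


class DegenerateInputError(DataError):
    """An operation received an input for which its result is undefined
    (e.g. a contrast ratio with an empty background class)."""


class NotTrainedError(ScmsegError, RuntimeError):
    """A classifier was used before being trained."""
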