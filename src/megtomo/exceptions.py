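"""Exception hierarchy for megtomo."""


class MegtomoError(Exception):
    """Base class for all megtomo errors."""


class NyquistError(MegtomoError, ValueError):
    """Requested frequency content above the Nyquist limit of the data."""


class NonFiniteDataError(MegtomoError, ValueError):
    """Input samples contain NaN or infinite values."""


class ZeroAmplitudeError(MegtomoError, ValueError):
    """An operation is undefined because every channel amplitude is zero."""


class GridCoverageError(MegtomoError, ValueError):
    """The source grid has no valid trial patterns under the sensor array."""


class GeometryError(MegtomoError, ValueError):
    """Inconsistent phantom or sensor geometry."""


class FieldPointError(MegtomoError, ValueError):
    """The field point is degenerate for the conductor model (F -> 0)."""
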