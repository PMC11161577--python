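"""Exception hierarchy."""


class FlyheartError(Exception):
    """Base class for package errors."""


class ParameterError(FlyheartError, ValueError):
    """An argument violates a documented bound."""


class GeometryError(FlyheartError, ValueError):
    """Requested heart geometry does not fit the frame."""


class DataError(FlyheartError, ValueError):
    """Dataset is empty, degenerate, or mis-shaped."""


class ExtractionError(FlyheartError, ValueError):
    """No usable diameter signal could be extracted."""


class InsufficientDataError(FlyheartError, ValueError):
    """Too few beats/samples for the requested statistic."""


class FormatError(FlyheartError, ValueError):
    """Unsupported or undecodable file format."""
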