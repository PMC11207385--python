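"""Exception hierarchy shared by all ocutilt modules."""


class OcutiltError(Exception):
    """Base class for all ocutilt errors."""


class ConfigError(OcutiltError):
    """A configuration value is out of its legal range or inconsistent."""


class InvalidGeometryError(OcutiltError):
    """A geometric precondition is violated (point behind camera, circle
    outside the image, patch over the frame border, ...)."""


class DetectionFailure(OcutiltError):
    """A detector found nothing usable in the frame.  Non-fatal: callers
    typically retry on the next frame."""


class DegenerateFitError(OcutiltError):
    """A regression problem is rank deficient (all abscissae equal)."""


class BaselineUnavailableError(OcutiltError):
    """No valid samples from which to estimate the 0-degree baseline."""
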