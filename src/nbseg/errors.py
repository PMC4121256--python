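"""Exception hierarchy shared across the package."""


class NbsegError(Exception):
    """Base class for all nbseg errors."""


class InvalidParameterError(NbsegError, ValueError):
    """A numeric parameter is outside its admissible range."""


class DegenerateInitializationError(NbsegError, ValueError):
    """An initial contour mask covers nothing or everything."""


class NoInterfaceError(NbsegError, ValueError):
    """A level-set field has no zero crossing (single-signed)."""


class InvalidWidthError(InvalidParameterError):
    """A narrow-band half-width violates the w > 2 pixel rule."""


class EmptyPhaseError(NbsegError, ValueError):
    """A region mean is requested for a phase with zero mass."""


class ContourVanishedError(NbsegError, RuntimeError):
    """The evolving contour disappeared (field became single-signed)."""


class EmptyMaskError(NbsegError, ValueError):
    """An overlap metric received an empty truth or prediction mask."""


class InvalidSpecError(NbsegError, ValueError):
    """A synthetic scene or noise specification is malformed."""


class InvalidInputError(NbsegError, ValueError):
    """Input arrays are inconsistent (shape/channel mismatch)."""
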