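"""Exception hierarchy for gmmda."""


class GmmdaError(Exception):
    """Base class for all gmmda errors."""


class DegenerateInputError(GmmdaError):
    """Input carries too little variation for the requested operation
    (constant image, zero trimmed spread, fewer distinct values than
    mixture components)."""


class InvalidGeometryError(GmmdaError):
    """Phantom geometry cannot be realised on the requested grid."""


class DimensionalityError(GmmdaError):
    """Volume is not a 3-D scalar lattice."""


class FormatError(GmmdaError):
    """File is not a readable NIfTI-1 volume, or its values violate the
    requested container's contract (e.g. non-integer labels)."""
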