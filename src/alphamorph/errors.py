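"""Exception hierarchy shared across alphamorph modules."""


class AlphamorphError(Exception):
    """Base class for all alphamorph errors."""


class DegenerateInputError(AlphamorphError):
    """Point set or raster too degenerate for the requested operation
    (fewer than 3 distinct points, collinear configuration, empty mask...)."""


class InternalConsistencyError(AlphamorphError):
    """A condition that is impossible for valid inputs was observed;
    indicates a bug, not bad data."""
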