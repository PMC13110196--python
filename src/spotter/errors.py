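"""Exception hierarchy for spotter."""


class SpotterError(Exception):
    """Base class for all spotter errors."""


class ConfigurationError(SpotterError):
    """A parameter, column mapping or config file is invalid."""


class DataError(SpotterError):
    """The input data violate a structural requirement."""


class GroupTooSmallError(DataError):
    """A requested time-series group has fewer eligible subjects than the minimum.

    Attributes
    ----------
    count : int
        Number of eligible subjects actually found.
    minimum : int
        Required minimum group size.
    """

    def __init__(self, count: int, minimum: int):
        self.count = count
        self.minimum = minimum
        super().__init__(
            f"group too small: {count} eligible subjects < minimum {minimum}"
        )
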