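"""Exception hierarchy for orgcount."""


class OrgcountError(Exception):
    """Base class for all orgcount-specific errors."""


class RegimeError(OrgcountError):
    """The requested computation requires a limiting distribution that does
    not exist for the given rates (e.g. k_fission >= gamma with no fusion)."""


class TruncationError(OrgcountError):
    """The stationary-distribution recurrence hit the support cap before the
    tail criterion was met."""

    def __init__(self, message: str, accumulated_mass: float, n_cap: int):
        super().__init__(message)
        self.accumulated_mass = accumulated_mass
        self.n_cap = n_cap


class DivergenceError(OrgcountError):
    """A simulated trajectory exceeded the divergence cap."""

    def __init__(self, message: str, time: float, count: int):
        super().__init__(message)
        self.time = time
        self.count = count


class OutOfModelError(OrgcountError):
    """An observation is outside the range attainable by the model
    (e.g. a Fano factor below 1 in the fusion-free model)."""
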